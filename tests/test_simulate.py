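import numpy as np
import pytest
from scipy import stats

from esmmtx import (
    GenerativeSpec,
    InjectionSpec,
    build_benchmark,
    compute_censor_threshold,
    generate_esm_gene,
    inject_signals,
    pair_and_filter,
)
from esmmtx.distributions import LomaxParams, lomax_cdf
from esmmtx.simulate import _stratified_split


class TestGenerativeGene:
    def test_null_gene_group_means_match(self, rng):
        spec = GenerativeSpec(
            n_samples=4000, n_subjects=1000, taxa_per_sample=1, beta=0.0,
            theta1=5.0, theta2=5.0, rho=1.0, phi=0.01, logD_sd=0.3, C=1e-8,
        )
        data, truth = generate_esm_gene(spec, rng)
        r = data.y / data.D  # remove the alpha=1 MGX effect
        m1, m0 = r[data.s == 1].mean(), r[data.s == 0].mean()
        pooled_se = r.std() * np.sqrt(1 / (data.s == 1).sum() + 1 / (data.s == 0).sum())
        assert abs(m1 - m0) < 4 * pooled_se

    def test_uncensored_mean_matches_mu(self, rng):
        # theta1 = 5 dominant: sample mean of y/mu ~ 1 within 3 SE
        spec = GenerativeSpec(
            n_samples=5000, n_subjects=5000, taxa_per_sample=1, theta1=5.0,
            rho=1.0, phi=1e-6, gamma=(0.0, 0.0, 0.0), logD_sd=0.5, C=1e-10,
        )
        data, truth = generate_esm_gene(spec, rng)
        ratio = data.y / truth["mu"]
        se = ratio.std() / np.sqrt(len(ratio))
        assert abs(ratio.mean() - 1.0) < 3 * se

    def test_zero_fraction_for_degenerate_component(self, rng):
        # theta2 -> 0 with rho < 1: component 2 censors with probability
        # given by the closed-form Lomax cdf at C
        spec = GenerativeSpec(
            n_samples=20000, n_subjects=20000, taxa_per_sample=1, theta1=50.0,
            theta2=1e-4, rho=0.5, phi=1e-6, gamma=(0.0, 0.0, 0.0),
            logD_mean=0.0, logD_sd=0.0, C=0.05,
        )
        data, truth = generate_esm_gene(spec, rng)
        mu = truth["mu"][0]
        p2 = lomax_cdf(spec.C, LomaxParams.from_mean_precision(mu, spec.theta2))
        p1 = lomax_cdf(spec.C, LomaxParams.from_mean_precision(mu, spec.theta1))
        expected = spec.rho * float(p1) + (1 - spec.rho) * float(p2)
        assert (data.y == 0).mean() == pytest.approx(expected, abs=0.02)

    def test_censoring_marks_values_below_threshold(self, rng):
        data, truth = generate_esm_gene(GenerativeSpec(n_samples=200, n_subjects=50, seed=1))
        pre = truth["y_precensor"]
        assert np.array_equal(data.y == 0, pre < truth["C"])
        assert np.all(data.y[data.y > 0] >= truth["C"])


class TestStratifiedSplit:
    @pytest.mark.parametrize("n_nonzero", [0, 1, 7, 50])
    def test_balance_within_both_strata(self, n_nonzero, rng):
        mask = np.zeros(101, dtype=bool)
        mask[:n_nonzero] = True
        s = _stratified_split(mask, rng)
        for stratum in (mask, ~mask):
            ones = s[stratum].sum()
            zeros = stratum.sum() - ones
            assert abs(ones - zeros) <= 1
            # deterministic odd rule: the extra sample goes to group 0
            if stratum.sum() % 2 == 1:
                assert zeros == ones + 1


class TestInjectSignals:
    def _backbone(self, rng, G=10, J=2, n=30):
        vals = rng.exponential(1.0, size=(G, J, n))
        vals[rng.random((G, J, n)) < 0.5] = 0.0
        return vals

    def test_multiplication_and_zeros(self, rng):
        vals = self._backbone(rng)
        spec = InjectionSpec(n_genes=10, fraction_de=0.4, signal=10.0, n_samples=30)
        out, truth, s = inject_signals(vals, spec, rng)
        assert truth["is_de"].sum() == 4
        assert set(truth["direction"]) <= {-1, 0, 1}
        for g in range(10):
            drn = truth["direction"].iloc[g]
            factor = 10.0 if drn == 1 else (0.1 if drn == -1 else 1.0)
            sel = s[g] == 1
            assert np.allclose(out[g][:, sel], vals[g][:, sel] * factor)
            assert np.allclose(out[g][:, ~sel], vals[g][:, ~sel])
            # zeros stay zero under multiplication
            assert np.array_equal(out[g] == 0, vals[g] == 0)

    def test_signal_one_changes_nothing(self, rng):
        vals = self._backbone(rng)
        out, truth, _ = inject_signals(
            vals, InjectionSpec(n_genes=10, signal=1.0, n_samples=30), rng
        )
        assert np.array_equal(out, vals)

    def test_truth_consistent_with_ratio(self, rng):
        vals = self._backbone(rng, G=6, J=3, n=200)
        spec = InjectionSpec(n_genes=6, fraction_de=0.5, signal=10.0, n_samples=200)
        out, truth, s = inject_signals(vals, spec, rng)
        for g in range(6):
            if truth["direction"].iloc[g] != 1:
                continue
            nz1 = out[g][:, s[g] == 1]
            nz0 = out[g][:, s[g] == 0]
            ratio = nz1[nz1 > 0].mean() / nz0[nz0 > 0].mean()
            assert np.log(ratio) == pytest.approx(np.log(10), abs=0.6)


class TestBuildBenchmark:
    def test_shapes_and_truth_counts(self):
        spec = InjectionSpec(n_genes=20, n_samples=40, seed=3)
        bundle = build_benchmark(spec)
        assert len(bundle.truth) == 20
        assert bundle.truth["is_de"].sum() == 8
        assert (bundle.truth["direction"] == 1).sum() == 4
        assert (bundle.truth["direction"] == -1).sum() == 4
        assert bundle.s_assignments.shape == (20, 40)
        assert len(bundle.meta) == 40

    def test_tables_readable_and_consistent(self):
        bundle = build_benchmark(InjectionSpec(n_genes=5, n_samples=20, seed=4))
        # aggregate rows equal taxon sums by construction
        from esmmtx import validate_aggregate_consistency

        report = validate_aggregate_consistency(bundle.mtx, tol=1e-6)
        assert not report["flagged"].any()
        C = compute_censor_threshold(bundle.mtx)
        assert C > 0
        # the bundle's own threshold is the backbone's detection limit and
        # never smaller than the post-injection minimum positive value
        assert bundle.censor_threshold >= C
        paired = pair_and_filter(bundle.mtx, bundle.mgx, bundle.meta, "G0001")
        assert paired is not None and np.all(paired.D > 0)

    def test_same_seed_identical_bundles(self, tmp_path):
        b1 = build_benchmark(InjectionSpec(n_genes=5, n_samples=20, seed=9))
        b2 = build_benchmark(InjectionSpec(n_genes=5, n_samples=20, seed=9))
        b1.write(tmp_path / "a")
        b2.write(tmp_path / "b")
        for name in ("mtx.tsv", "mgx.tsv", "metadata.tsv", "truth.tsv", "s_assignments.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_user_supplied_backbone_replaces_generative(self):
        donor = build_benchmark(InjectionSpec(n_genes=6, n_samples=24, seed=5))
        spec = InjectionSpec(n_genes=4, n_samples=24, seed=6, signal=10.0)
        bundle = build_benchmark(spec, backbone_mtx=donor.mtx, backbone_mgx=donor.mgx)
        assert len(bundle.truth) == 4
        # the injected table is built from the donor's abundances: nonzero
        # cells of null genes match the donor exactly
        null = bundle.truth.loc[bundle.truth.is_de == 0, "gene_id"].iloc[0]
        donor_rows = donor.mtx.taxon_rows(null).to_numpy()
        new_rows = bundle.mtx.taxon_rows(null).to_numpy()
        assert np.allclose(np.sort(new_rows[new_rows > 0]), np.sort(donor_rows[donor_rows > 0]))
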