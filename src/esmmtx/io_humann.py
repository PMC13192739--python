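"""Reading, validating and pairing HUMAnN-style stratified abundance tables.

A stratified gene-family table has one aggregate row per gene family
(``UniRef90_XXXX``), per-taxon rows (``UniRef90_XXXX|g_Genus.s_Species``) and
optionally an unclassified row (``UniRef90_XXXX|unclassified``); columns are
samples and values are nonnegative CPM. Differential-expression modelling
works on per-gene *paired* observations: for every (sample, taxon) cell the
RNA abundance ``y`` together with the DNA abundance ``D`` of the same gene
family in the same sample and taxon.

Filtering follows the MGX-based rule: a (sample, taxon) observation is kept
only when its DNA abundance is positive. This removes pairs where both RNA
and DNA are zero, and also pairs showing apparent RNA expression without
detectable gene copies (a likely technical artifact). RNA zeros with
positive DNA are retained and later treated as left-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedTable",
    "read_stratified_table",
    "write_stratified_table",
    "validate_aggregate_consistency",
    "read_metadata",
    "PairedGeneData",
    "pair_and_filter",
    "compute_censor_threshold",
    "gene_eligibility_filter",
]

AGGREGATE = "aggregate"
TAXON = "taxon"
UNCLASSIFIED = "unclassified"


def classify_feature(feature_id: str) -> tuple[str, str, str]:
    """Split a feature id into (gene_id, suffix, row_kind)."""
    if "|" not in feature_id:
        return feature_id, "", AGGREGATE
    gene, suffix = feature_id.split("|", 1)
    kind = UNCLASSIFIED if suffix == "unclassified" else TAXON
    return gene, suffix, kind


@dataclass
class StratifiedTable:
    """A gene-family x sample abundance matrix with stratification metadata.

    ``values`` is a DataFrame indexed by the verbatim feature id; ``row_kind``
    aligns with its index. Taxon suffixes are stored verbatim and matched as
    full strings between MTX and MGX tables.
    """

    values: pd.DataFrame
    row_kind: pd.Series
    gene_ids: pd.Series = field(default=None)
    taxon_suffix: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.gene_ids is None or self.taxon_suffix is None:
            parsed = [classify_feature(f) for f in self.values.index]
            self.gene_ids = pd.Series([p[0] for p in parsed], index=self.values.index)
            self.taxon_suffix = pd.Series([p[1] for p in parsed], index=self.values.index)
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            bad = np.argwhere(~(np.isfinite(arr) & (arr >= 0)))[0]
            raise ValueError(
                f"negative or non-finite value at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.gene_ids))

    def taxon_rows(self, gene_id: str | None = None) -> pd.DataFrame:
        mask = self.row_kind == TAXON
        if gene_id is not None:
            mask &= self.gene_ids == gene_id
        return self.values.loc[mask]


def read_stratified_table(path: str | Path) -> StratifiedTable:
    """Read a tab-separated stratified table; first column is the feature id.

    The first-column header is arbitrary (HUMAnN versions vary). Negative or
    non-numeric body values and duplicate feature ids are errors.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    feat = df.iloc[:, 0].astype(str)
    if feat.duplicated().any():
        dup = feat[feat.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    body = df.iloc[:, 1:]
    values = pd.DataFrame(index=pd.Index(feat, name="feature_id"))
    for col in body.columns:
        try:
            values[col] = pd.to_numeric(body[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            bad = body[col][pd.to_numeric(body[col], errors="coerce").isna()]
            row = feat.iloc[bad.index[0]] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            ) from exc
        if (values[col] < 0).any():
            row = feat.iloc[int(np.argmax(values[col].to_numpy() < 0))]
            raise ValueError(f"{path}: negative value in column {col!r}, row {row!r}")
    kinds = pd.Series(
        [classify_feature(f)[2] for f in values.index], index=values.index
    )
    return StratifiedTable(values=values, row_kind=kinds)


def write_stratified_table(table: StratifiedTable, path: str | Path) -> None:
    """Write a table in the HUMAnN dialect with round-trip-exact formatting.

    Values are written with ``repr`` precision (shortest string that parses
    back to the same float), so write-then-read is bit-identical.
    """
    with open(path, "w") as fh:
        fh.write("# Gene Family\t" + "\t".join(table.sample_ids) + "\n")
        arr = table.values.to_numpy()
        for i, feat in enumerate(table.values.index):
            fh.write(feat + "\t" + "\t".join(repr(float(v)) for v in arr[i]) + "\n")


def validate_aggregate_consistency(
    table: StratifiedTable, tol: float = 1e-3
) -> pd.DataFrame:
    """Per gene and sample, residual = aggregate - (taxon rows + unclassified).

    Returns a tidy frame with columns gene_id, sample_id, aggregate,
    stratified_sum, residual, flagged. Genes with stratified rows but no
    aggregate row are skipped (they cannot be checked).
    """
    if not (table.row_kind == AGGREGATE).any():
        raise ValueError("table contains no aggregate rows")
    records = []
    agg_genes = set(table.gene_ids[table.row_kind == AGGREGATE])
    for gene in table.genes:
        if gene not in agg_genes:
            continue
        gmask = table.gene_ids == gene
        agg = table.values.loc[gmask & (table.row_kind == AGGREGATE)].iloc[0]
        strat = table.values.loc[gmask & (table.row_kind != AGGREGATE)].sum(axis=0)
        resid = agg - strat
        for sample in table.sample_ids:
            records.append(
                {
                    "gene_id": gene,
                    "sample_id": sample,
                    "aggregate": agg[sample],
                    "stratified_sum": strat[sample],
                    "residual": resid[sample],
                    "flagged": abs(resid[sample]) > tol,
                }
            )
    return pd.DataFrame.from_records(records)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV.

    Requires columns ``sample_id``, ``subject_id`` and ``group`` (the binary
    DE variable); remaining columns are treated as covariates. Samples with
    missing values are dropped (listwise deletion) with a logged count.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    for col in ("sample_id", "subject_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    n0 = len(meta)
    meta = meta.dropna()
    meta.attrs["n_dropped_missing"] = n0 - len(meta)
    if not set(np.unique(meta["group"])) <= {0, 1}:
        raise ValueError("group must be binary 0/1")
    return meta.reset_index(drop=True)


@dataclass
class PairedGeneData:
    """One gene's filtered paired MTX/MGX observations.

    Observation arrays are flat over retained (sample, taxon) cells; sample-
    level arrays (``s``, ``X``, ``subject``) are aligned per observation.
    ``X`` includes the intercept column.
    """

    gene_id: str
    y: np.ndarray          # MTX CPM, >= 0 (zeros are censored)
    D: np.ndarray          # MGX CPM, > 0 after filtering
    sample_index: np.ndarray
    taxon_index: np.ndarray
    s: np.ndarray          # binary DE indicator per observation
    X: np.ndarray          # (n_obs, 1+p) design incl. intercept
    subject: np.ndarray    # dense subject index per observation
    sample_ids: list[str]
    taxa: list[str]
    subject_ids: list[str]
    covariate_names: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxa_per_sample(self) -> np.ndarray:
        return np.bincount(self.sample_index, minlength=self.n_samples)


def pair_and_filter(
    mtx: StratifiedTable,
    mgx: StratifiedTable,
    meta: pd.DataFrame,
    gene_id: str,
    filter_mode: str = "mgx_positive",
    s_override: np.ndarray | None = None,
) -> PairedGeneData | None:
    """Build per-gene paired observations and apply abundance filtering.

    ``filter_mode='mgx_positive'`` keeps observations with D > 0 (the model's
    rule, which subsumes dropping double zeros); ``'semi_strict'`` drops only
    pairs with both MTX and MGX zero (the Gaussian baseline's rule). Taxa are
    the intersection of the gene's MTX and MGX taxa; samples are those present
    in both tables and in the metadata. Returns None when the gene is absent
    from either table or no observation survives.

    ``s_override`` replaces the metadata ``group`` column with a per-sample
    vector aligned to the metadata rows (used by the injection benchmark,
    where the DE indicator is gene-specific).
    """
    if filter_mode not in ("mgx_positive", "semi_strict"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    mtx_rows = mtx.taxon_rows(gene_id)
    mgx_rows = mgx.taxon_rows(gene_id)
    if mtx_rows.empty or mgx_rows.empty:
        return None
    mtx_tax = {classify_feature(f)[1]: f for f in mtx_rows.index}
    mgx_tax = {classify_feature(f)[1]: f for f in mgx_rows.index}
    taxa = sorted(set(mtx_tax) & set(mgx_tax))
    if not taxa:
        return None
    samples = [
        sid
        for sid in meta["sample_id"]
        if sid in mtx.values.columns and sid in mgx.values.columns
    ]
    if not samples:
        return None
    meta_idx = meta.set_index("sample_id").loc[samples]
    Y = mtx_rows.loc[[mtx_tax[t] for t in taxa], samples].to_numpy()
    Dm = mgx_rows.loc[[mgx_tax[t] for t in taxa], samples].to_numpy()
    if filter_mode == "mgx_positive":
        keep = Dm > 0
    else:
        keep = (Dm > 0) | (Y > 0)
    tj, si = np.nonzero(keep)
    if len(si) == 0:
        return None
    cov_names = [
        c for c in meta.columns if c not in ("sample_id", "subject_id", "group")
    ]
    if s_override is not None:
        s_by_sample = np.asarray(s_override, dtype=float)
        if len(s_by_sample) != len(meta):
            raise ValueError("s_override must align with metadata rows")
        s_series = pd.Series(s_by_sample, index=meta["sample_id"]).loc[samples]
    else:
        s_series = meta_idx["group"].astype(float)
    # densify to retained samples/taxa/subjects only
    used_samples = sorted(set(si))
    sample_map = {old: new for new, old in enumerate(used_samples)}
    used_taxa = sorted(set(tj))
    taxon_map = {old: new for new, old in enumerate(used_taxa)}
    sample_ids = [samples[i] for i in used_samples]
    subj_raw = meta_idx["subject_id"].to_numpy()
    subj_used = [subj_raw[i] for i in used_samples]
    subject_ids = sorted(set(subj_used))
    subj_map = {s: k for k, s in enumerate(subject_ids)}
    Xcov = meta_idx[cov_names].to_numpy(dtype=float) if cov_names else np.empty((len(samples), 0))
    n_obs = len(si)
    X = np.empty((n_obs, 1 + len(cov_names)))
    X[:, 0] = 1.0
    sample_index = np.array([sample_map[i] for i in si])
    taxon_index = np.array([taxon_map[j] for j in tj])
    X[:, 1:] = Xcov[si]
    return PairedGeneData(
        gene_id=gene_id,
        y=Y[tj, si].astype(float),
        D=Dm[tj, si].astype(float),
        sample_index=sample_index,
        taxon_index=taxon_index,
        s=s_series.to_numpy()[si],
        X=X,
        subject=np.array([subj_map[subj_raw[i]] for i in si]),
        sample_ids=sample_ids,
        taxa=[taxa[j] for j in used_taxa],
        subject_ids=subject_ids,
        covariate_names=cov_names,
    )


def compute_censor_threshold(mtx: StratifiedTable) -> float:
    """Minimum positive taxon-level MTX abundance across all genes.

    Interpreted as the minimum detectable abundance in CPM; observed zeros
    are treated as latent abundances below this threshold. Computed on the
    raw table before any gene filtering.
    """
    vals = mtx.taxon_rows().to_numpy()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no positive taxon-level MTX abundance in table")
    return float(pos.min())


def gene_eligibility_filter(
    paired: PairedGeneData | None,
    min_shared_taxa: int = 2,
    min_per_category: int = 5,
    require_nonzero_mtx_per_group: bool = True,
) -> tuple[bool, str]:
    """Gene-selection criteria applied after pairing and filtering.

    Requires >= ``min_shared_taxa`` taxa shared between MTX and MGX; every
    binary variable (the DE indicator and binary covariates) to have both
    categories with more than ``min_per_category`` observations; binary
    variables pairwise non-identical (no perfect collinearity); and, when
    requested, at least one nonzero MTX value in each DE group so log fold
    changes are well defined.
    """
    if paired is None or paired.n_obs == 0:
        return False, "no_paired_observations"
    if paired.n_taxa < min_shared_taxa:
        return False, f"shared_species<{min_shared_taxa}"
    binaries = {"s": paired.s}
    for k, name in enumerate(paired.covariate_names):
        col = paired.X[:, 1 + k]
        if set(np.unique(col)) <= {0.0, 1.0}:
            binaries[name] = col
    for name, col in binaries.items():
        counts = [(col == 0).sum(), (col == 1).sum()]
        if min(counts) <= min_per_category:
            return False, f"binary_{name}_category<={min_per_category}"
    names = list(binaries)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = binaries[names[i]], binaries[names[j]]
            if np.array_equal(a, b) or np.array_equal(a, 1 - b):
                return False, f"collinear_{names[i]}_{names[j]}"
    if require_nonzero_mtx_per_group:
        for grp in (0, 1):
            if not np.any(paired.y[paired.s == grp] > 0):
                return False, f"no_nonzero_mtx_group{grp}"
    return True, "eligible"
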