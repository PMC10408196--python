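"""Abundance tables, sample metadata, and the file dialects that carry them.

Two tabular dialects are supported:

* merged taxonomic profiles: tab-separated, first column a pipe-delimited
  clade lineage (``k__...|p__...|...|s__...``), one column per sample,
  values either proportions (columns sum to 1) or percentages (sum to 100);
* stratified functional profiles: tab-separated, first column a feature id
  that is either unstratified (``PWY-1``), stratified per contributing
  taxon (``PWY-1|g__X.s__Y`` or ``PWY-1|unclassified``), or one of the
  bookkeeping rows ``UNMAPPED`` / ``UNINTEGRATED``; values in copies per
  million (CPM).

Sample metadata is a plain TSV with columns ``sample_id, subject_id,
cohort_id, cohort_type, day, phase``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNITS = ("relative", "counts", "cpm")
LEVELS = ("species", "genus", "pathway", "ko")
COHORT_TYPES = ("control", "antibiotic", "lifestyle")
PHASES = ("baseline", "post")

LEVEL_PREFIX = {"species": "s__", "genus": "g__"}
SPECIAL_FEATURES = ("UNMAPPED", "UNINTEGRATED")

CLOSURE_TOL = 1e-6

METADATA_COLUMNS = ["sample_id", "subject_id", "cohort_id", "cohort_type", "day", "phase"]


class ProfileFormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def is_stratified(feature_id: str) -> bool:
    """True for per-taxon contribution rows of a functional profile."""
    return "|" in feature_id and not is_special(feature_id)


def is_special(feature_id: str) -> bool:
    """True for the non-biological CPM bookkeeping rows."""
    root = feature_id.split("|", 1)[0]
    return root in SPECIAL_FEATURES


def parent_feature(feature_id: str) -> str:
    """Unstratified parent of a stratified row (identity for unstratified)."""
    return feature_id.split("|", 1)[0]


def terminal_clade(lineage: str) -> str:
    """Last clade of a pipe-delimited lineage, e.g. ``s__Bacteroides_vulgatus``."""
    return lineage.rsplit("|", 1)[-1]


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix with unit and level semantics.

    ``data`` is indexed by feature id (full lineage for taxa, possibly
    stratified ids for functions) with one column per sample.
    """

    data: pd.DataFrame
    unit: str
    level: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ProfileFormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ProfileFormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ProfileFormatError("non-numeric values in abundance table")
        if np.any(~np.isfinite(values)):
            raise ProfileFormatError("non-finite values in abundance table")
        if (values < 0).any():
            raise ProfileFormatError("negative abundances are not allowed")
        if self.unit == "relative" and len(self.data):
            sums = self.unstratified().sum(axis=0).to_numpy()
            nonzero = sums > 0
            if np.any(np.abs(sums[nonzero] - 1.0) > 1e-4):
                raise ProfileFormatError(
                    "unit='relative' requires unstratified columns to sum to 1 "
                    f"(observed sums in [{sums.min():.4g}, {sums.max():.4g}])"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def terminal_names(self) -> list[str]:
        return [terminal_clade(f) for f in self.feature_ids]

    # -- views -----------------------------------------------------------
    def unstratified(self) -> pd.DataFrame:
        """Biological, unstratified rows only (community totals).

        Taxa tables (species/genus) have no stratified rows: the pipes in
        a clade lineage are taxonomy, not per-taxon stratification.
        """
        if self.level in ("species", "genus"):
            return self.data
        keep = [f for f in self.data.index if not is_stratified(f) and not is_special(f)]
        return self.data.loc[keep]

    def stratified(self) -> pd.DataFrame:
        if self.level in ("species", "genus"):
            return self.data.iloc[0:0]
        keep = [f for f in self.data.index if is_stratified(f)]
        return self.data.loc[keep]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return AbundanceTable(self.data[list(sample_ids)].copy(), self.unit, self.level)

    def relative(self) -> "AbundanceTable":
        """Total-sum-scaled copy (no-op if already relative)."""
        if self.unit == "relative":
            return self
        return normalize(self, "tss")


@dataclass
class SampleMetadata:
    """Per-sample study annotations keyed by sample id."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ProfileFormatError(f"metadata missing columns: {missing}")
        f = self.frame.copy()
        f["day"] = f["day"].astype(int)
        bad_type = set(f["cohort_type"]) - set(COHORT_TYPES)
        if bad_type:
            raise ProfileFormatError(f"unknown cohort_type values: {sorted(bad_type)}")
        bad_phase = set(f["phase"]) - set(PHASES)
        if bad_phase:
            raise ProfileFormatError(f"unknown phase values: {sorted(bad_phase)}")
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ProfileFormatError(f"duplicate sample ids in metadata: {dups[:5]}")
        dup_day = f.duplicated(subset=["cohort_id", "subject_id", "day"])
        if dup_day.any():
            rows = f.loc[dup_day, ["subject_id", "day"]].to_records(index=False).tolist()
            raise ProfileFormatError(f"duplicate (subject, day) within cohort: {rows[:5]}")
        for (cohort, ctype), grp in f.groupby(["cohort_id", "cohort_type"]):
            if ctype != "control":
                no_base = grp.groupby("subject_id")["phase"].apply(lambda p: "baseline" not in set(p))
                if no_base.any():
                    subs = no_base[no_base].index.tolist()
                    raise ProfileFormatError(
                        f"cohort {cohort}: subjects without a baseline sample: {subs[:5]}"
                    )
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.frame["subject_id"]))

    def for_samples(self, sample_ids) -> "SampleMetadata":
        sub = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleMetadata(sub.copy())

    def subject_samples(self, subject_id: str) -> pd.DataFrame:
        """Samples of one subject ordered by collection day."""
        sub = self.frame[self.frame["subject_id"] == subject_id]
        return sub.sort_values("day").reset_index(drop=True)

    def paired_samples(self, k: int = 2) -> tuple[dict[str, list[str]], list[str]]:
        """First ``k`` samples (by day) per subject.

        Returns (subject -> k sample ids) for subjects with >= k samples and
        the list of excluded subjects (fewer than k samples).
        """
        pairs: dict[str, list[str]] = {}
        excluded: list[str] = []
        for subject, grp in self.frame.groupby("subject_id"):
            ordered = grp.sort_values("day")["sample_id"].tolist()
            if len(ordered) >= k:
                pairs[subject] = ordered[:k]
            else:
                excluded.append(subject)
        return pairs, excluded


def align(table: AbundanceTable, metadata: SampleMetadata) -> tuple[AbundanceTable, SampleMetadata]:
    """Check table/metadata sample agreement; mismatches are a hard error."""
    tset, mset = set(table.sample_ids), set(metadata.sample_ids)
    only_t = sorted(tset - mset)
    only_m = sorted(mset - tset)
    if only_t or only_m:
        raise ProfileFormatError(
            f"sample mismatch: {len(only_t)} only in table {only_t[:5]}, "
            f"{len(only_m)} only in metadata {only_m[:5]}"
        )
    order = [s for s in metadata.sample_ids]
    return table.subset_samples(order), metadata


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, dtype={0: str})
    if df.shape[1] < 2:
        raise ProfileFormatError(f"{path}: expected a feature column plus sample columns")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ProfileFormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    return df.astype(float)


def read_taxonomic_profile(path, level: str = "species") -> AbundanceTable:
    """Read a merged taxonomic table, keeping rows that terminate at ``level``.

    The percent dialect (columns summing to ~100) is auto-detected and
    converted to proportions; columns are then total-sum scaled so the
    closure invariant holds exactly.
    """
    if level not in LEVEL_PREFIX:
        raise ValueError(f"level must be one of {tuple(LEVEL_PREFIX)}")
    df = _read_tsv(path)
    df = df[~df.index.str.startswith("#")] if df.index.dtype == object else df
    prefix = LEVEL_PREFIX[level]
    keep = [f for f in df.index if terminal_clade(f).startswith(prefix)]
    df = df.loc[keep]
    if df.empty:
        warnings.warn(f"{path}: no rows at level {level!r}; returning an empty table")
        return AbundanceTable(df, "relative", level)
    sums = df.sum(axis=0)
    nz = sums[sums > 0]
    if len(nz) and np.allclose(nz, 100.0, rtol=0.05):
        df = df / 100.0
    elif len(nz) and not np.allclose(nz, 1.0, rtol=0.05):
        raise ProfileFormatError(
            f"{path}: mixed or unrecognised units (column sums in "
            f"[{sums.min():.4g}, {sums.max():.4g}]; expected ~1 or ~100)"
        )
    colsum = df.sum(axis=0)
    df = df.div(colsum.where(colsum > 0, 1.0), axis=1)
    return AbundanceTable(df, "relative", level)


def write_taxonomic_profile(table: AbundanceTable, path, percent: bool = False) -> None:
    df = table.data * (100.0 if percent else 1.0)
    df.index.name = "clade_name"
    df.to_csv(path, sep="\t")


def read_stratified_function_profile(path, level: str = "pathway") -> AbundanceTable:
    """Read a stratified functional table (CPM), validating stratification.

    Stratified rows without their unstratified parent, or exceeding the
    parent total beyond tolerance, are rejected.
    """
    df = _read_tsv(path)
    parents = {f for f in df.index if not is_stratified(f) and not is_special(f)}
    orphans = sorted({parent_feature(f) for f in df.index if is_stratified(f)} - parents)
    if orphans:
        raise ProfileFormatError(
            f"{path}: stratified rows without an unstratified parent: {orphans[:5]}"
        )
    for parent in parents:
        strat = [f for f in df.index if is_stratified(f) and parent_feature(f) == parent]
        if strat:
            excess = df.loc[strat].sum(axis=0) - df.loc[parent]
            if (excess > 1e-6 * np.maximum(df.loc[parent], 1.0)).any():
                raise ProfileFormatError(
                    f"{path}: stratified rows of {parent!r} exceed the unstratified total"
                )
    return AbundanceTable(df, "cpm", level)


def write_stratified_function_profile(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = "# Pathway"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize(table: AbundanceTable, scheme: str) -> AbundanceTable:
    """Column normalisation: ``tss`` (sum to 1) or ``cpm`` (sum to 1e6).

    All-zero columns are left as zeros with a warning.
    """
    if scheme not in ("tss", "cpm"):
        raise ValueError("scheme must be 'tss' or 'cpm'")
    df = table.data
    sums = df.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample column(s) left unnormalised")
    scale = 1.0 if scheme == "tss" else 1e6
    out = df.div(sums.where(~zero, 1.0), axis=1) * scale
    out[df.columns[zero]] = 0.0
    unit = "relative" if scheme == "tss" else "cpm"
    return AbundanceTable(out, unit, table.level)


def contribution_ratios(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample stratified/unstratified ratio for every stratified row.

    Rows are stratified feature ids; entries are NaN where the parent
    community total is zero.
    """
    strat = table.stratified()
    if strat.empty:
        return strat
    parents = strat.index.map(parent_feature)
    denom = table.data.loc[parents].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, strat.to_numpy(dtype=float) / denom, np.nan)
    return pd.DataFrame(ratio, index=strat.index, columns=strat.columns)
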