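"""Spectral-count grading of bait-capture interactors.

Candidate interactors from an affinity-purification MS experiment are
scored by comparing exclusive spectral counts (ESC) between bait replicates
and control-bait replicates:

1. Proteins whose mean ESC over control replicates strictly exceeds the
   mean over bait replicates are *excluded* outright (control-dominant
   background binders).
2. The remaining proteins receive a two-sided two-sample Student's t-test
   (pooled variance; Welch optional) of bait counts versus control counts.
3. Grades follow p-value bands: A (p < 0.1), B (0.1 <= p <= 0.25),
   C (0.25 < p < 0.5), contaminant (p >= 0.5). A protein detected
   (count > 0) in at most one bait replicate is a contaminant regardless of
   its p-value.

Counts are used untransformed. Zero-variance degenerate cases take the
limiting value of the t statistic: equal group means give p = 1, unequal
means with zero pooled variance give p = 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from epinet.errors import StructuralError

__all__ = [
    "GRADES",
    "SpectralCountTable",
    "filter_control_dominant",
    "grade_from_p",
    "grade_interactors",
    "summarize_grades",
    "write_graded",
    "read_graded",
]

GRADES = ("A", "B", "C", "contaminant", "excluded")


class SpectralCountTable:
    """Integer ESC matrix (proteins x samples) with per-sample roles.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, indexed by unique protein ID, one
        column per sample.
    roles : Series or mapping
        Sample ID -> ``"bait"`` or ``"control"``, covering every column.
    """

    def __init__(self, counts: pd.DataFrame, roles: pd.Series | dict):
        roles = pd.Series(roles, name="role")
        if not counts.index.is_unique:
            raise StructuralError("protein IDs must be unique")
        if not counts.columns.is_unique:
            raise StructuralError("sample IDs must be unique")
        missing = set(counts.columns) - set(roles.index)
        if missing:
            raise StructuralError(f"samples without a role: {sorted(missing)}")
        bad = set(roles.loc[list(counts.columns)]) - {"bait", "control"}
        if bad:
            raise StructuralError(f"unknown sample roles: {sorted(bad)}")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer) or (arr < 0).any()):
            raise StructuralError("counts must be non-negative integers")
        self.counts = counts
        self.roles = roles.loc[list(counts.columns)]

    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def bait_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == "bait"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == "control"]

    def require_groups(self, min_per_group: int = 1) -> None:
        if len(self.bait_samples) < min_per_group or len(self.control_samples) < min_per_group:
            raise StructuralError(
                f"need at least {min_per_group} bait and {min_per_group} control "
                f"samples, got {len(self.bait_samples)} bait / "
                f"{len(self.control_samples)} control"
            )

    def subset(self, protein_ids) -> "SpectralCountTable":
        return SpectralCountTable(self.counts.loc[protein_ids], self.roles)

    # --- serialization ----------------------------------------------------

    def to_files(self, esc_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(esc_path, sep="\t")
        meta = pd.DataFrame(
            {
                "sample_id": list(self.counts.columns),
                "role": [self.roles[s] for s in self.counts.columns],
                "replicate": [
                    int(s.rsplit("_", 1)[1]) if "_" in s and s.rsplit("_", 1)[1].isdigit() else i + 1
                    for i, s in enumerate(self.counts.columns)
                ],
            }
        )
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, esc_path: str | Path, samples_path: str | Path) -> "SpectralCountTable":
        counts = pd.read_csv(esc_path, sep="\t", index_col=0)
        counts.index.name = "protein_id"
        meta = pd.read_csv(samples_path, sep="\t")
        if "sample_id" not in meta.columns or "role" not in meta.columns:
            raise StructuralError("samples file must have sample_id and role columns")
        roles = pd.Series(meta["role"].values, index=meta["sample_id"].values, name="role")
        return cls(counts.astype(np.int64), roles)


def filter_control_dominant(
    table: SpectralCountTable,
) -> tuple[SpectralCountTable, set[str]]:
    """Drop proteins whose mean control ESC strictly exceeds the mean bait ESC.

    Equality is kept ("higher" is strict). Row order of survivors is
    preserved. Returns the filtered table and the excluded protein IDs.
    """
    table.require_groups(1)
    mean_bait = table.counts[table.bait_samples].mean(axis=1)
    mean_control = table.counts[table.control_samples].mean(axis=1)
    dominant = mean_control > mean_bait
    excluded = set(table.protein_ids[dominant])
    return table.subset(table.protein_ids[~dominant]), excluded


def grade_from_p(p: float, n_bait_detected: int) -> str:
    """Map a p-value and bait detection count to a grade label.

    The single-entry contaminant rule (detected in <= 1 bait replicate)
    takes precedence over the p-value ladder; the ladder is A on [0, 0.1),
    B on [0.1, 0.25], C on (0.25, 0.5), contaminant on [0.5, 1].
    """
    if n_bait_detected <= 1:
        return "contaminant"
    if p < 0.1:
        return "A"
    if p <= 0.25:
        return "B"
    if p < 0.5:
        return "C"
    return "contaminant"


def _pooled_t_pvalues(bait: np.ndarray, control: np.ndarray, welch: bool) -> np.ndarray:
    """Vectorized two-sided two-sample t-test p-values per protein row,
    with the zero-variance limits applied."""
    import warnings

    with warnings.catch_warnings():
        # degenerate (zero-variance) rows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(bait, control, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: scipy yields nan when the (pooled) variance is zero
    var_b = bait.var(axis=1, ddof=1)
    var_c = control.var(axis=1, ddof=1)
    zero_var = (var_b == 0) & (var_c == 0)
    diff = bait.mean(axis=1) - control.mean(axis=1)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    p = np.where(zero_var & (diff != 0), 0.0, p)
    return p


def grade_interactors(
    table: SpectralCountTable,
    welch: bool = False,
    single_entry_across_all: bool = False,
) -> pd.DataFrame:
    """Grade every protein in an ESC table.

    Applies the control-dominance exclusion first, then the t-test ladder
    to the survivors. Excluded proteins are carried through with
    ``grade="excluded"`` and no p-value.

    Parameters
    ----------
    table : SpectralCountTable
    welch : bool
        Use Welch's unequal-variance t-test instead of the classic
        pooled-variance Student's test.
    single_entry_across_all : bool
        Apply the single-entry contaminant rule to detections across all
        samples instead of bait replicates only.

    Returns
    -------
    DataFrame indexed by protein_id with columns
    ``grade, p_value, mean_bait, mean_control, n_bait_detected``.
    """
    table.require_groups(2)
    kept, excluded = filter_control_dominant(table)

    bait = kept.counts[kept.bait_samples].to_numpy(dtype=float)
    control = kept.counts[kept.control_samples].to_numpy(dtype=float)

    mean_bait_all = table.counts[table.bait_samples].mean(axis=1)
    mean_control_all = table.counts[table.control_samples].mean(axis=1)
    if single_entry_across_all:
        n_detected_all = (table.counts > 0).sum(axis=1)
    else:
        n_detected_all = (table.counts[table.bait_samples] > 0).sum(axis=1)

    if len(kept.protein_ids):
        p_kept = pd.Series(_pooled_t_pvalues(bait, control, welch), index=kept.protein_ids)
    else:
        p_kept = pd.Series(dtype=float)

    records = []
    for pid in table.protein_ids:
        if pid in excluded:
            grade, p = "excluded", np.nan
        else:
            p = float(p_kept[pid])
            grade = grade_from_p(p, int(n_detected_all[pid]))
        records.append(
            {
                "protein_id": pid,
                "grade": grade,
                "p_value": p,
                "mean_bait": float(mean_bait_all[pid]),
                "mean_control": float(mean_control_all[pid]),
                "n_bait_detected": int((table.counts.loc[pid, table.bait_samples] > 0).sum()),
            }
        )
    out = pd.DataFrame.from_records(records).set_index("protein_id")
    return out


def summarize_grades(graded: pd.DataFrame) -> dict:
    """Tally grades into a summary dict whose counts sum to the input size."""
    counts = {g: 0 for g in GRADES}
    if len(graded):
        counts.update(graded["grade"].value_counts().to_dict())
    total = int(len(graded))
    summary = {
        "counts": {g: int(counts.get(g, 0)) for g in GRADES},
        "total_proteins": total,
        "total_excluded": int(counts.get("excluded", 0)),
    }
    assert sum(summary["counts"].values()) == total
    return summary


def write_graded(graded: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write ``graded_interactors.tsv`` and ``grade_summary.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "graded_interactors.tsv"
    graded.to_csv(tsv, sep="\t", float_format="%.12g")
    summary_path = outdir / "grade_summary.json"
    summary_path.write_text(json.dumps(summarize_grades(graded), indent=1, sort_keys=True) + "\n")
    return {"graded": tsv, "summary": summary_path}


def read_graded(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")
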