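"""Residual-based calling of dsRNA-pulldown enrichment and depletion.

For each mutant-vs-control comparison the module computes per-gene log2
fold changes in both assays (total RNA-seq and dsRNA-seq), regresses the
dsRNA fold change on the total fold change by ordinary least squares, and
flags genes whose standardized residual exceeds a z threshold (default
2.5) as enriched (positive) or depleted (negative).  Calls consistent
across the two mutants are intersected, and G/C composition of the call
sets is compared against all genes with a Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NormalizationError

CONDITIONS = ("control", "mutant1", "mutant2")


@dataclass
class SampleSheet:
    """Sample metadata: one row per column of the count matrix."""

    table: pd.DataFrame  # columns: sample, assay, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample", "assay", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"sample sheet missing columns {sorted(missing)}")

    def samples(self, assay: str, condition: str) -> list[str]:
        t = self.table
        sel = t[(t.assay == assay) & (t.condition == condition)]
        return list(sel["sample"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (DESeq-style).

    The reference is the per-gene geometric mean over samples; each
    sample's factor is the median ratio to this reference over genes with
    nonzero counts in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no gene has nonzero counts in all samples")
    sub = mat[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2fc(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    assay: str,
    mutant: str,
    control: str = "control",
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene log2 fold change (mutant vs control) of normalized means."""
    mutant_samples = sheet.samples(assay, mutant)
    control_samples = sheet.samples(assay, control)
    if len(mutant_samples) < 2 or len(control_samples) < 2:
        raise InputError(
            f"assay {assay!r}: need >=2 replicates for {mutant!r} and {control!r}"
        )
    cols = mutant_samples + control_samples
    if factors is None:
        factors = size_factors(counts[cols])
    norm = counts[cols] / factors[cols]
    mut_mean = norm[mutant_samples].mean(axis=1)
    ctl_mean = norm[control_samples].mean(axis=1)
    lfc = np.log2(mut_mean + pseudocount) - np.log2(ctl_mean + pseudocount)
    lfc.name = f"lfc_{assay}_{mutant}"
    return lfc


def fold_change_table(
    total: pd.DataFrame,
    dsrna: pd.DataFrame,
    sheet: SampleSheet,
    mutant: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Paired (lfc_total, lfc_dsrna) per gene for one comparison."""
    if not total.index.equals(dsrna.index):
        raise InputError("total and dsRNA matrices have different gene universes")
    return pd.DataFrame(
        {
            "lfc_total": log2fc(total, sheet, "total", mutant, pseudocount=pseudocount),
            "lfc_dsrna": log2fc(dsrna, sheet, "dsrna", mutant, pseudocount=pseudocount),
        }
    )


def residual_calls(
    fc: pd.DataFrame,
    z_threshold: float = 2.5,
    studentized: bool = False,
) -> pd.DataFrame:
    """Flag genes deviating from the dsRNA-vs-total fold-change regression.

    Fits ``lfc_dsrna ~ a + b * lfc_total`` by OLS.  The standardized
    residual is the raw residual divided by the sample SD of residuals;
    with ``studentized=True`` it is additionally leverage-adjusted
    (internally studentized).  Genes with standardized residual above
    ``z_threshold`` are called enriched, below ``-z_threshold`` depleted.
    A degenerate fit (zero residual SD) yields no calls.
    """
    if len(fc) < 3:
        raise InputError("need >=3 genes for the regression")
    x = fc["lfc_total"].to_numpy(dtype=float)
    y = fc["lfc_dsrna"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise InputError("non-finite fold changes")
    if np.ptp(x) == 0:
        raise InputError("lfc_total is constant; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sd = float(resid.std(ddof=1))
    if sd == 0.0:
        z = np.zeros_like(resid)
    elif studentized:
        n = len(x)
        h = 1.0 / n + (x - x.mean()) ** 2 / ((x - x.mean()) ** 2).sum()
        z = resid / (sd * np.sqrt(1.0 - h))
    else:
        z = resid / sd
    call = np.where(z > z_threshold, "enriched",
                    np.where(z < -z_threshold, "depleted", "none"))
    if sd == 0.0:
        call[:] = "none"
    return pd.DataFrame(
        {
            "residual": resid,
            "standardized_residual": z,
            "call": call,
        },
        index=fc.index,
    )


def consistent_calls(
    calls_m1: pd.DataFrame, calls_m2: pd.DataFrame
) -> dict[str, dict[str, list[str]]]:
    """Venn decomposition of calls across the two mutant comparisons.

    Returns, separately for enriched and depleted, the genes called in
    mutant1 only, mutant2 only, and consistently in both (same direction).
    """
    if not calls_m1.index.equals(calls_m2.index):
        raise InputError("call tables have different gene universes")
    out: dict[str, dict[str, list[str]]] = {}
    for direction in ("enriched", "depleted"):
        s1 = set(calls_m1.index[calls_m1.call == direction])
        s2 = set(calls_m2.index[calls_m2.call == direction])
        out[direction] = {
            "m1_only": sorted(s1 - s2),
            "m2_only": sorted(s2 - s1),
            "shared": sorted(s1 & s2),
        }
    return out


def gc_content(seq: str) -> float:
    """Fraction of G/C nucleotides in a sequence."""
    if not seq:
        raise InputError("empty sequence has no G/C proportion")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; exact for small tie-free samples."""
    exact = (
        len(a) <= 25 and len(b) <= 25
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def gc_test(
    enriched: set[str],
    depleted: set[str],
    gc: pd.Series,
) -> pd.DataFrame:
    """Compare G/C proportions of call sets against all genes.

    ``gc`` maps every gene to its G/C proportion.  Each nonempty call set
    is compared to the full gene set with a two-sided Mann-Whitney U test;
    empty sets are skipped with a warning.
    """
    all_gc = gc.to_numpy(dtype=float)
    rows = [
        {
            "set": "all",
            "n": len(gc),
            "median_gc": float(np.median(all_gc)),
            "p_value": np.nan,
        }
    ]
    for name, ids in (("enriched", enriched), ("depleted", depleted)):
        if not ids:
            warnings.warn(f"{name} set empty; comparison skipped")
            continue
        missing = set(ids) - set(gc.index)
        if missing:
            raise InputError(f"{name} ids missing from G/C table: {sorted(missing)[:5]}")
        vals = gc.loc[sorted(ids)].to_numpy(dtype=float)
        rows.append(
            {
                "set": name,
                "n": len(vals),
                "median_gc": float(np.median(vals)),
                "p_value": _mannwhitney(vals, all_gc),
            }
        )
    return pd.DataFrame(rows)
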