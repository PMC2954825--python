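"""Allele-specific expression (TaqMan qPCR) and flow-cytometry statistics.

qPCR side: an allele-discriminating TaqMan assay reports one Ct per allele
channel.  A standard curve built from serial mixes of two homozygous
genomic DNAs maps the channel difference ``dCt = Ct_A - Ct_B`` to a
log2 allelic ratio; unknown cDNA samples are read off the curve.  A
heterozygous genomic-DNA control (equal template for both alleles) must
recover a ratio of 1.0 — the standard validation of the regression.  An
NMD contrast compares untreated cells (allele-B transcript degraded, ratio
below 1) with translation-blocked cells (degradation inhibited, ratio back
to ~1).

Flow-cytometry side: surface MHC class I (HLA-ABC) mean fluorescence
intensity standardized by a constitutive B-cell marker (CD19), outliers
removed per experiment x genotype group by the 1.5 x IQR fence, genotype
effect assessed by per-experiment Welch t-tests and an additive two-factor
ANOVA (genotype + experiment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "allelic_ratio",
    "nmd_effect",
    "iqr_filter",
    "MfiModel",
    "MfiResults",
    "mfi_inference",
]


# ---------------------------------------------------------------------------
# qPCR standard curves and allelic ratios


@dataclass(frozen=True)
class StandardCurve:
    """log2(B:A ratio) = slope * dCt + intercept, with fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def ratio(self, dct: float) -> float:
        return float(2.0 ** (self.slope * dct + self.intercept))


def fit_standard_curve(
    standards: pd.DataFrame,
    *,
    min_r2: float = 0.9,
) -> StandardCurve:
    """Least-squares fit of log2 mix ratio on dCt over the standards.

    ``standards`` rows need ``fraction`` (mix fraction of allele B, in
    (0, 1)), ``ct_a`` and ``ct_b``.  At least three distinct fractions are
    required; the fit is refused when R^2 falls below ``min_r2``.
    """
    df = standards.dropna(subset=["fraction", "ct_a", "ct_b"])
    fractions = df["fraction"].astype(float)
    if fractions.nunique() < 3:
        raise ValueError("standard curve needs >= 3 distinct mix fractions")
    if ((fractions <= 0) | (fractions >= 1)).any():
        raise ValueError("mix fractions must lie strictly in (0, 1)")
    y = np.log2(fractions / (1.0 - fractions))
    x = (df["ct_a"] - df["ct_b"]).astype(float)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < min_r2:
        raise ValueError(f"standard curve rejected: R^2 = {r2:.3f} < {min_r2}")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(df),
        r_squared=r2,
    )


@dataclass(frozen=True)
class AllelicRatio:
    ratio: float          # mean B:A over replicates
    sem: float
    n_replicates: int
    flagged_missing: bool = False


def allelic_ratio(sample: pd.DataFrame, curve: StandardCurve) -> AllelicRatio:
    """B:A expression ratio for one sample (triplicate mean with SEM).

    ``sample`` rows are replicate wells with ``ct_a`` / ``ct_b``.  Missing
    replicates are dropped and flagged; the ratio is the mean of
    per-replicate curve readouts.
    """
    df = sample.copy()
    n_in = len(df)
    df = df.dropna(subset=["ct_a", "ct_b"])
    if df.empty:
        raise ValueError("no complete replicates for this sample")
    ratios = np.asarray(
        [curve.ratio(dct) for dct in (df["ct_a"] - df["ct_b"]).astype(float)]
    )
    sem = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return AllelicRatio(
        ratio=float(ratios.mean()),
        sem=sem,
        n_replicates=len(ratios),
        flagged_missing=len(ratios) < n_in,
    )


def nmd_effect(
    untreated: dict[str, AllelicRatio],
    blocked: dict[str, AllelicRatio],
    *,
    deficit_threshold: float = 0.8,
    restored_band: tuple[float, float] = (0.8, 1.25),
) -> pd.DataFrame:
    """Per-cell-line NMD contrast between untreated and NMD-blocked arms.

    A cell line is "NMD-consistent" when its untreated B:A ratio falls
    below ``deficit_threshold`` (allele-B transcript depleted) while the
    blocked ratio returns into ``restored_band`` (similar expression from
    both alleles once decay is inhibited).  Equal ratios in both arms give
    "no NMD signal".  Unpaired cell lines are an error.
    """
    if set(untreated) != set(blocked):
        missing = set(untreated) ^ set(blocked)
        raise ValueError(f"unpaired samples between treatment arms: {sorted(missing)}")
    rows = []
    for cell in sorted(untreated):
        u, b = untreated[cell], blocked[cell]
        consistent = u.ratio < deficit_threshold and (
            restored_band[0] <= b.ratio <= restored_band[1]
        )
        rows.append(
            {
                "cell_line": cell,
                "ratio_untreated": u.ratio,
                "sem_untreated": u.sem,
                "ratio_blocked": b.ratio,
                "sem_blocked": b.sem,
                "verdict": "NMD-consistent" if consistent else "no NMD signal",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flow cytometry


def iqr_filter(
    values: pd.Series | np.ndarray,
    groups: pd.DataFrame | pd.Series | None = None,
    k: float = 1.5,
    min_group: int = 4,
) -> np.ndarray:
    """Tukey-fence outlier mask within experiment x genotype groups.

    Within each group, values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are
    dropped (mask False).  Quartiles use linear interpolation — outlier
    sets depend on the quartile convention, so it is fixed here.  Groups
    smaller than ``min_group`` pass through untouched.
    """
    vals = pd.Series(np.asarray(values, dtype=float))
    if groups is None:
        keys = pd.Series(0, index=vals.index)
    elif isinstance(groups, pd.DataFrame):
        keys = groups.astype(str).agg("|".join, axis=1).reset_index(drop=True)
    else:
        keys = pd.Series(groups).astype(str).reset_index(drop=True)
    mask = np.ones(len(vals), dtype=bool)
    for _, idx in vals.groupby(keys).groups.items():
        sub = vals.loc[idx]
        if len(sub) < min_group:
            continue
        q1, q3 = np.percentile(sub, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        mask[np.asarray(idx, dtype=int)] &= ((sub >= lo) & (sub <= hi)).to_numpy()
    return mask


@dataclass
class MfiResults:
    """Fitted genotype/experiment inference for one MFI measure."""

    measure: str
    anova: pd.DataFrame                 # additive two-factor ANOVA table
    p_genotype: float
    p_experiment: float
    t_tests: pd.DataFrame               # per-experiment Welch AA vs BB
    box_summary: pd.DataFrame           # quartiles/mean/outliers per group
    n_removed_outliers: int

    def summary(self) -> str:
        lines = [
            f"Two-factor ANOVA on {self.measure} (AA vs BB, additive):",
            f"  genotype   p = {self.p_genotype:.4f}",
            f"  experiment p = {self.p_experiment:.4f}",
            "Per-experiment Welch t-tests (AA vs BB):",
        ]
        for _, r in self.t_tests.iterrows():
            lines.append(
                f"  experiment {r['experiment']}: t = {r['t']:.3f}, p = {r['p']:.4f}"
            )
        return "\n".join(lines)


class MfiModel:
    """Standardized-MFI inference model.

    Construct from a records table with columns ``sample``, ``genotype``
    (AA/AB/BB), ``experiment``, ``hla_mfi``, ``cd19_mfi``; ``fit`` runs the
    outlier filter, the additive two-factor ANOVA on the AA/BB homozygotes,
    and the per-experiment Welch t-tests, returning :class:`MfiResults`.
    """

    def __init__(self, records: pd.DataFrame, measure: str = "standardized"):
        required = {"sample", "genotype", "experiment", "hla_mfi", "cd19_mfi"}
        if not required.issubset(records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        if (records[["hla_mfi", "cd19_mfi"]] <= 0).any().any():
            raise ValueError("MFI values must be positive")
        if measure not in ("HLA", "CD19", "standardized"):
            raise ValueError("measure must be HLA, CD19, or standardized")
        df = records.copy()
        df["standardized"] = df["hla_mfi"] / df["cd19_mfi"]
        df["value"] = {
            "HLA": df["hla_mfi"],
            "CD19": df["cd19_mfi"],
            "standardized": df["standardized"],
        }[measure]
        self.data = df.reset_index(drop=True)
        self.measure = measure

    def fit(self, iqr_k: float = 1.5) -> MfiResults:
        df = self.data
        mask = iqr_filter(df["value"], df[["experiment", "genotype"]], k=iqr_k)
        removed = int((~mask).sum())
        kept = df.loc[mask].reset_index(drop=True)

        homo = kept[kept["genotype"].isin(["AA", "BB"])]
        for exp_id, sub in homo.groupby("experiment"):
            present = set(sub["genotype"])
            if present != {"AA", "BB"}:
                raise ValueError(
                    f"experiment {exp_id!r} lacks genotype {sorted({'AA','BB'} - present)}"
                )
        model = smf.ols("value ~ C(genotype) + C(experiment)", data=homo).fit()
        anova = sm.stats.anova_lm(model, typ=2)

        t_rows = []
        for exp_id, sub in homo.groupby("experiment"):
            aa = sub.loc[sub["genotype"] == "AA", "value"]
            bb = sub.loc[sub["genotype"] == "BB", "value"]
            t, p = stats.ttest_ind(aa, bb, equal_var=False)
            t_rows.append(
                {"experiment": exp_id, "t": float(t), "p": float(p),
                 "n_AA": len(aa), "n_BB": len(bb)}
            )

        box_rows = []
        for (exp_id, gt), sub in kept.groupby(["experiment", "genotype"]):
            q1, med, q3 = np.percentile(sub["value"], [25, 50, 75], method="linear")
            box_rows.append(
                {
                    "experiment": exp_id,
                    "genotype": gt,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "mean": float(sub["value"].mean()),
                    "n": len(sub),
                }
            )

        return MfiResults(
            measure=self.measure,
            anova=anova,
            p_genotype=float(anova.loc["C(genotype)", "PR(>F)"]),
            p_experiment=float(anova.loc["C(experiment)", "PR(>F)"]),
            t_tests=pd.DataFrame(t_rows),
            box_summary=pd.DataFrame(box_rows),
            n_removed_outliers=removed,
        )


def mfi_inference(records: pd.DataFrame, measure: str = "standardized") -> MfiResults:
    """Convenience wrapper: ``MfiModel(records, measure).fit()``."""
    return MfiModel(records, measure).fit()
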