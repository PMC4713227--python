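"""Quantification of the two experimental readouts: qPCR panels and neuron counts.

qPCR quantification follows the dilution-factor method: each gene has a
standard curve with an amplification efficiency e (printed as a fractional
value near 1; the per-cycle amplification fold is 1 + e, i.e. close to the
canonical doubling) and an intercept c0 (the cycle count at unit template
quantity).  A measured threshold cycle Ct converts to a dilution factor
``fold**(c0 - Ct)``; per replicate, factors are normalised to the mean
factor over the olfactory-receptor panel (reference genes such as ACT5C and
GAPDH2 are carried for completeness but excluded from that mean).

The inverse map -- simulating Ct values from known abundances through the
same curves plus Gaussian cycle noise -- permits closed-loop testing: at
zero noise, quantification recovers abundance ratios exactly.

Count statistics mirror the study design: a classic pooled-variance
two-sample t-test per gene (Welch available by flag) and one-way ANOVA with
a post-hoc table of all pairwise two-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fate_mapping import _data_path

__all__ = [
    "StandardCurve",
    "CtMatrix",
    "RelQuant",
    "load_default_curves",
    "simulate_ct",
    "relative_quantity",
    "genotype_comparison",
    "count_anova",
]


@dataclass(frozen=True)
class StandardCurve:
    """Per-gene qPCR standard curve.

    ``efficiency`` is the printed fractional amplification efficiency
    (values near 1.0); ``fold`` converts it to the per-cycle amplification
    fold under the adopted convention (fold = 1 + efficiency by default,
    fold = efficiency when ``efficiency_is_fold``).
    """

    gene: str
    efficiency: float
    intercept: float
    role: str = "or_panel"  # or_panel | reference

    def fold(self, efficiency_is_fold: bool = False) -> float:
        f = self.efficiency if efficiency_is_fold else 1.0 + self.efficiency
        if not (0.8 < f <= 2.2):
            raise ValueError(
                f"per-cycle fold {f:.3f} for {self.gene} outside the "
                "conventional (0.8, 2.2] range"
            )
        return f


def load_default_curves() -> dict:
    """The bundled 22-gene panel of amplification efficiencies."""
    df = pd.read_csv(_data_path("qpcr_curves.tsv"), sep="\t")
    return {
        row.gene: StandardCurve(row.gene, float(row.efficiency),
                                float(row.intercept), row.role)
        for row in df.itertuples()
    }


@dataclass
class CtMatrix:
    """gene x replicate threshold cycles, one column per replicate."""

    frame: pd.DataFrame  # index gene, columns replicate labels
    group: str = ""

    def validate(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("Ct values must be finite and positive")


@dataclass
class RelQuant:
    """Normalised dilution factors (per replicate OR-panel mean = 1)."""

    frame: pd.DataFrame
    group: str = ""

    def of(self, gene: str) -> np.ndarray:
        return self.frame.loc[gene].to_numpy(dtype=float)


def simulate_ct(abundances: dict, curves: dict, sigma: float, replicates: int,
                seed: int, efficiency_is_fold: bool = False,
                group: str = "") -> CtMatrix:
    """Generate Ct values from relative template abundances.

    Ct = c0 - log(abundance) / log(fold) + N(0, sigma) per replicate.
    Deterministic given the seed; sigma = 0 gives exact curve inversion.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    bad = [g for g, a in abundances.items() if not (a > 0)]
    if bad:
        raise ValueError(f"abundances must be positive, offending genes: {bad}")
    missing = [g for g in abundances if g not in curves]
    if missing:
        raise ValueError(f"no standard curve for gene(s): {missing}")

    rng = np.random.default_rng(seed)
    genes = list(abundances)
    data = np.empty((len(genes), replicates))
    for i, g in enumerate(genes):
        curve = curves[g]
        fold = curve.fold(efficiency_is_fold)
        ct0 = curve.intercept - np.log(abundances[g]) / np.log(fold)
        data[i] = ct0 + (rng.normal(0.0, sigma, replicates) if sigma > 0 else 0.0)
    frame = pd.DataFrame(data, index=genes,
                         columns=[f"rep{j + 1}" for j in range(replicates)])
    ct = CtMatrix(frame=frame, group=group)
    ct.validate()
    return ct


def relative_quantity(ct: CtMatrix, curves: dict,
                      efficiency_is_fold: bool = False) -> RelQuant:
    """Dilution factors from Ct via standard curves, OR-panel normalised.

    factor = fold**(c0 - Ct); each replicate's factors are then divided by
    that replicate's mean over the OR panel (reference genes excluded from
    the mean but reported normalised to it).
    """
    missing = [g for g in ct.frame.index if g not in curves]
    if missing:
        raise ValueError(f"no standard curve for gene(s): {missing}")
    factors = pd.DataFrame(index=ct.frame.index, columns=ct.frame.columns, dtype=float)
    for g in ct.frame.index:
        curve = curves[g]
        fold = curve.fold(efficiency_is_fold)
        factors.loc[g] = fold ** (curve.intercept - ct.frame.loc[g].to_numpy(dtype=float))
    panel = [g for g in ct.frame.index if curves[g].role == "or_panel"]
    if not panel:
        raise ValueError("no OR-panel genes present to normalise against")
    norm = factors.loc[panel].mean(axis=0)
    return RelQuant(frame=factors.div(norm, axis=1), group=ct.group)


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def genotype_comparison(groups: dict, welch: bool = False) -> pd.DataFrame:
    """Per-gene fold change and two-tailed two-sample t between two genotypes.

    ``groups`` maps exactly two genotype labels to RelQuant objects sharing
    a gene index.  The classic pooled-variance t is the default, matching
    the study's statistics; Welch by flag.  Fold change is the ratio of
    group means (first listed genotype over the second).
    """
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 genotypes, got {len(groups)}")
    (la, qa), (lb, qb) = groups.items()
    if list(qa.frame.index) != list(qb.frame.index):
        raise ValueError("gene sets differ between genotypes")
    if qa.frame.shape[1] < 2 or qb.frame.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    rows = []
    for g in qa.frame.index:
        a, b = qa.of(g), qb.of(g)
        t, p = _ttest(a, b, welch)
        fold = np.mean(a) / np.mean(b) if np.mean(b) != 0 else np.inf
        rows.append({"gene": g, "fold": fold, "t": t, "p": p,
                     "contrast": f"{la}/{lb}"})
    return pd.DataFrame(rows).set_index("gene")


def count_anova(groups: dict, welch: bool = False) -> dict:
    """One-way ANOVA across genotype count vectors, with post-hoc t table.

    Returns F, degrees of freedom, p and a DataFrame of all pairwise
    two-tailed t-tests.  With zero within-group variance everywhere the
    F statistic is undefined; this is flagged rather than raised.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")

    k = len(arrays)
    ns = np.array([v.size for v in arrays.values()])
    n_total = int(ns.sum())
    grand = np.concatenate(list(arrays.values())).mean()
    ssb = float(sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values()))
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in arrays.values()))
    df_between, df_within = k - 1, n_total - k
    degenerate = ssw == 0.0
    if degenerate:
        F = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / df_between) / (ssw / df_within)
        p = float(stats.f.sf(F, df_between, df_within))

    rows = []
    labels = list(arrays)
    for i in range(k):
        for j in range(i + 1, k):
            t, pt = _ttest(arrays[labels[i]], arrays[labels[j]], welch)
            rows.append({"group_a": labels[i], "group_b": labels[j], "t": t, "p": pt})
    return {
        "F": F, "df_between": df_between, "df_within": df_within, "p": p,
        "ss_between": ssb, "ss_within": ssw,
        "zero_within_variance": degenerate,
        "posthoc": pd.DataFrame(rows),
    }
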