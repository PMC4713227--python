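"""Developmental-transcriptome differential screen with trend concordance.

The screen contrasts three genotypes (wild type, heterozygote, homozygote)
at three early developmental stages.  Its core logic -- the contribution
re-implemented here -- is the filtering cascade applied per stage:

1.  receptor exclusion (ORs/IRs/GRs are readouts, not candidate regulators);
2.  a count floor: the maximum of the three genotype mean normalised counts
    must reach ``min_count`` (default 20);
3.  trend concordance: the homozygote-vs-wild-type and
    homozygote-vs-heterozygote contrasts must agree in sign (a zero ratio
    can never be concordant).  The heterozygote carries a balancer
    chromosome and shows no phenotype, so requiring both contrasts removes
    balancer artifacts;
4.  a relaxed significance cutoff (unadjusted p < 0.1) in both contrasts.

Genes passing all four at a stage are "misregulated" there; the three
stage-wise pass sets are partitioned into the seven non-empty regions of a
Venn diagram.  Normalisation is the median-of-ratios size-factor estimator.
The per-gene test is a pluggable two-group comparison on log-transformed
normalised counts; the claim of the screen is the filter cascade, not the
test statistic.  A negative-binomial generator with planted homozygote-only
effects provides closed-loop calibration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ScreenResult",
    "size_factors",
    "de_compare",
    "concordance_filter",
    "venn_partition",
    "simulate_counts",
    "run_screen",
]

GENOTYPES = ("wt", "het", "hom")
STAGES = ("T1", "T2", "T3")

#: order in which filter failures are attributed
FAILURE_ORDER = ("receptor_excluded", "low_count", "discordant", "nonsignificant")


@dataclass
class CountMatrix:
    """gene x sample integer counts with a sample sheet."""

    counts: pd.DataFrame  # index gene, columns sample names
    samples: pd.DataFrame  # index sample name; columns genotype, stage, replicate

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample sheet does not match count columns")
        combos = self.samples.groupby(["genotype", "stage"]).size()
        if (combos < 1).any():
            raise ValueError("every (genotype, stage) needs >= 1 sample")

    def of_stage(self, stage: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["stage"] == stage]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])

    def samples_of(self, genotype: str) -> list:
        return list(self.samples.index[self.samples["genotype"] == genotype])


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; each
    sample's factor is the median over reference genes of
    count / geometric-mean-of-that-gene-across-samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene is nonzero in all samples; cannot estimate size factors")
    ref = counts[nonzero]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=cm.counts.columns, name="size_factor")


def _normalized(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    return cm.counts.div(sf, axis=1)


def de_compare(cm: CountMatrix, sf: pd.Series, group_a, group_b) -> pd.DataFrame:
    """Two-group comparison on normalised counts, per gene.

    Returns log2 ratio of normalised group means (pseudo-count 1) and a
    two-sided p from a pooled t-test on log2(normalised count + 1).  Genes
    with no variance and equal means get p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    norm = _normalized(cm, sf)
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # flat genes handled below
        res = stats.ttest_ind(la, lb, axis=1)
        pvals = np.asarray(res.pvalue)
    flat = (np.ptp(la, axis=1) == 0) & (np.ptp(lb, axis=1) == 0)
    equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    pvals = np.where(flat & equal, 1.0, pvals)
    pvals = np.where(flat & ~equal, 0.0, pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.DataFrame({"log2fc": log2fc, "p": pvals}, index=cm.counts.index)


@dataclass
class ScreenResult:
    """Per-gene screen outcome for one stage."""

    table: pd.DataFrame  # columns: mean_wt, mean_het, mean_hom, log2fc_wt,
    #          p_wt, log2fc_het, p_het, passed, reason
    stage: str = ""

    def passing(self) -> set:
        return set(self.table.index[self.table["passed"]])


def concordance_filter(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       cm: CountMatrix, receptor_list, sf: pd.Series | None = None,
                       min_count: float = 20.0, p_cut: float = 0.1,
                       stage: str = "") -> ScreenResult:
    """Apply the four-step cascade to the two contrasts (hom-vs-wt, hom-vs-het).

    pass iff not a receptor AND max genotype mean normalised count >=
    min_count AND sign(log2fc_a) == sign(log2fc_b) != 0 AND both p < p_cut.
    Failures carry the first failing reason in the documented order.
    """
    if list(results_a.index) != list(results_b.index) or \
            set(results_a.index) != set(cm.counts.index):
        raise ValueError("contrasts and counts must share one gene universe")
    sf = size_factors(cm) if sf is None else sf
    norm = _normalized(cm, sf)
    means = {
        g: norm[cm.samples_of(g)].mean(axis=1) for g in ("wt", "het", "hom")
    }
    max_mean = pd.concat(means.values(), axis=1).max(axis=1)
    receptors = set(receptor_list)

    sign_a = np.sign(results_a["log2fc"].to_numpy())
    sign_b = np.sign(results_b["log2fc"].to_numpy())
    rows = []
    for i, gene in enumerate(results_a.index):
        reason = ""
        if gene in receptors:
            reason = "receptor_excluded"
        elif max_mean.loc[gene] < min_count:
            reason = "low_count"
        elif sign_a[i] == 0 or sign_a[i] != sign_b[i]:
            reason = "discordant"
        elif not (results_a["p"].iloc[i] < p_cut and results_b["p"].iloc[i] < p_cut):
            reason = "nonsignificant"
        rows.append({
            "gene": gene,
            "mean_wt": means["wt"].loc[gene], "mean_het": means["het"].loc[gene],
            "mean_hom": means["hom"].loc[gene],
            "log2fc_wt": results_a["log2fc"].iloc[i], "p_wt": results_a["p"].iloc[i],
            "log2fc_het": results_b["log2fc"].iloc[i], "p_het": results_b["p"].iloc[i],
            "passed": reason == "", "reason": reason,
        })
    return ScreenResult(pd.DataFrame(rows).set_index("gene"), stage=stage)


def venn_partition(pass_sets: dict) -> dict:
    """Exact partition of stage-wise pass sets into the 7 Venn regions.

    ``pass_sets`` maps stage names to gene sets; the result maps region
    keys like ``"T1"``, ``"T1&T2"``, ``"T1&T2&T3"`` to disjoint gene sets
    whose union is the union of all inputs.
    """
    stages = list(pass_sets)
    if len(stages) != 3:
        raise ValueError(f"expected 3 stage sets, got {len(stages)}")
    regions = {}
    for r in range(1, 4):
        for inside in itertools.combinations(stages, r):
            outside = [s for s in stages if s not in inside]
            region = set.intersection(*(set(pass_sets[s]) for s in inside))
            for s in outside:
                region -= set(pass_sets[s])
            regions["&".join(inside)] = region
    return regions


def simulate_counts(n_genes: int, design: dict | None = None,
                    planted: dict | None = None, dispersion: float = 0.05,
                    seed: int = 0, base_mean_log: float = 4.0,
                    base_mean_sdlog: float = 1.5,
                    planted_mean_log: float = 5.3,
                    planted_mean_sdlog: float = 0.5) -> tuple:
    """Negative-binomial counts for the 3-genotype x 3-stage design.

    Planted effects apply in the homozygote only (the heterozygote tracks
    the wild type, which is what makes the two-contrast concordance filter
    work).  ``planted`` maps gene index -> (set of stages, log2 effect).
    Background base means are log-normal; planted genes draw their base
    mean from a higher, tighter log-normal (misregulated developmental
    genes are expressed genes).  Returns (CountMatrix, truth DataFrame).
    """
    design = design or {"genotypes": list(GENOTYPES), "stages": list(STAGES),
                        "replicates": 3}
    genotypes, stages = design["genotypes"], design["stages"]
    reps = design["replicates"]
    if n_genes < 1 or reps < 1 or not genotypes or not stages:
        raise ValueError("invalid design")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    planted = planted or {}

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(base_mean_log, base_mean_sdlog, n_genes)
    for idx in planted:
        base[idx] = rng.lognormal(planted_mean_log, planted_mean_sdlog)

    sample_rows, columns = [], []
    data = np.zeros((n_genes, len(genotypes) * len(stages) * reps), dtype=int)
    col = 0
    nb_n = 1.0 / dispersion
    for stage in stages:
        for genotype in genotypes:
            for rep in range(1, reps + 1):
                mu = base.copy()
                if genotype == "hom":
                    for idx, (stage_set, effect) in planted.items():
                        if stage in stage_set:
                            mu[idx] *= 2.0 ** effect
                p = nb_n / (nb_n + mu)
                data[:, col] = rng.negative_binomial(nb_n, p)
                name = f"{stage}_{genotype}_{rep}"
                columns.append(name)
                sample_rows.append({"sample": name, "genotype": genotype,
                                    "stage": stage, "replicate": rep})
                col += 1

    counts = pd.DataFrame(data, index=genes, columns=columns)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    truth_rows = [
        {"gene": genes[idx], "stages": "&".join(sorted(stage_set)),
         "log2_effect": effect}
        for idx, (stage_set, effect) in planted.items()
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene", "stages", "log2_effect"])
    cm = CountMatrix(counts, samples)
    cm.validate()
    return cm, truth


def run_screen(cm: CountMatrix, receptor_list=(), min_count: float = 20.0,
               p_cut: float = 0.1) -> dict:
    """Full per-stage screen: normalise, contrast, filter, Venn-partition.

    Returns {"results": {stage: ScreenResult}, "venn": partition dict}.
    """
    results = {}
    for stage in sorted(set(cm.samples["stage"])):
        sub = cm.of_stage(stage)
        sf = size_factors(sub)
        res_wt = de_compare(sub, sf, sub.samples_of("hom"), sub.samples_of("wt"))
        res_het = de_compare(sub, sf, sub.samples_of("hom"), sub.samples_of("het"))
        results[stage] = concordance_filter(res_wt, res_het, sub, receptor_list,
                                            sf=sf, min_count=min_count,
                                            p_cut=p_cut, stage=stage)
    venn = venn_partition({s: r.passing() for s, r in results.items()}) \
        if len(results) == 3 else {}
    return {"results": results, "venn": venn}
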