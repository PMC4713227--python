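"""Synthetic per-antenna neuron counts under any genotype, with clonal mosaics.

Each antenna carries a stereotyped census of sensilla subtypes; every
sensillum houses exactly one neuron per constituent ORN class, so a class
count equals the count of its sensilla.  Counts per subtype are drawn
Poisson around an expected value (no overdispersion by default).

Only the at4 census is anchored to printed data: roughly 60 Or47b neurons
per wild-type antenna, rising to about 90 in rn mutants, fixing the rn-null
ectopic at4 complement at +30 (half the wild-type census).  All other
subtype counts are plausible defaults summing near the printed whole-organ
totals and are calibration inputs, not claims.

A fate delta rescales the census: territorially expanded fates gain an
ectopic complement (default +50% of their wild-type census, generalising
the at4 anchor), reduced fates keep 50%, lost fates none.  Within-ring Bab
conversions move census mass from donor to recipient fates inside one ring.

Clonal mosaics (MARCM) assign each sensillum to the clone independently
with probability f.  When the clone carries a secondary loss of function,
ectopic sensilla whose ring code requires that factor fail to adopt the
ectopic fate inside clones, while the endogenous census is spared (the
endogenous fate is robust to the loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fate_mapping import ReporterTable, _data_path, expected_fate_map, load_table1
from .perturbation_predictor import FateDelta

__all__ = [
    "CompositionTable",
    "CloneModel",
    "AntennaSample",
    "load_default_composition",
    "effective_census",
    "expected_class_mean",
    "simulate_antennae",
    "class_counts",
]

#: factor whose loss a secondary clone genotype removes, per supported label
_SECONDARY_FACTORS = {"Bar_null": "Bar", "ap_null": "Ap", "bab_null": "Bab"}

DEFAULT_EXPANSION_GAIN = 0.5  # ectopic complement as a fraction of the WT census
DEFAULT_REDUCTION_RETENTION = 0.5
DEFAULT_CONVERSION_FRACTION = 0.5  # census fraction a donor fate cedes per conversion


@dataclass
class CompositionTable:
    """Expected sensilla census per antenna plus subtype -> ORN classes."""

    expected: dict  # sensilla -> expected count per antenna
    classes: dict  # sensilla -> tuple of ORN class names

    def validate(self) -> None:
        missing = set(self.expected) ^ set(self.classes)
        if missing:
            raise ValueError(f"census/class tables disagree on subtypes: {sorted(missing)}")
        if any(v < 0 for v in self.expected.values()):
            raise ValueError("expected counts must be non-negative")

    def total_sensilla(self) -> float:
        return float(sum(self.expected.values()))

    def total_neurons(self) -> float:
        return float(sum(self.expected[s] * len(self.classes[s]) for s in self.expected))

    def sensilla_of_class(self, orn_class: str) -> list:
        out = [s for s, cls in self.classes.items() if orn_class in cls]
        if not out:
            raise KeyError(f"unknown ORN class {orn_class!r}")
        return out


def load_default_composition(table: ReporterTable | None = None) -> CompositionTable:
    """Default census: at4 = 60 (anchored to the printed Or47b count),
    others free defaults; ~425 sensilla, ~1100 neurons per antenna."""
    table = table or load_table1()
    census = pd.read_csv(_data_path("composition.tsv"), sep="\t")
    expected = dict(zip(census["sensilla"], census["expected_count"].astype(float)))
    classes = {
        s: tuple(dict.fromkeys(table.frame.loc[table.frame["sensilla"] == s, "orn_class"]))
        for s in expected
    }
    comp = CompositionTable(expected=expected, classes=classes)
    comp.validate()
    return comp


@dataclass(frozen=True)
class CloneModel:
    """Bernoulli clone assignment per sensillum with a secondary genotype."""

    clone_fraction: float
    secondary: str = "Bar_null"

    def validate(self) -> None:
        if not (0 <= self.clone_fraction <= 1):
            raise ValueError(f"clone_fraction must be in [0,1], got {self.clone_fraction}")
        if self.secondary not in _SECONDARY_FACTORS:
            raise ValueError(
                f"unsupported secondary genotype {self.secondary!r}; "
                f"expected one of {sorted(_SECONDARY_FACTORS)}"
            )


@dataclass
class AntennaSample:
    genotype: str
    counts: dict  # ORN class -> neuron count
    sensilla_counts: dict  # sensilla -> surviving sensilla count
    clone_sensilla: int
    total_sensilla: int
    seed: int


def _census_components(comp: CompositionTable, delta: FateDelta | None,
                       expansion_gain: float, reduction_retention: float,
                       conversion_fraction: float) -> tuple:
    """Split the census into (endogenous, ectopic) expectations per subtype."""
    endo = dict(comp.expected)
    ecto = {s: 0.0 for s in comp.expected}
    if delta is None:
        return endo, ecto
    for s in comp.expected:
        if s not in delta.calls:
            continue
        call = delta.calls[s]
        if call.status == "lost":
            endo[s] = 0.0
        elif call.status == "reduced":
            if call.converted_to:  # within-ring conversion: cede mass to siblings
                ceded = comp.expected[s] * conversion_fraction
                endo[s] = comp.expected[s] - ceded
                share = ceded / len(call.converted_to)
                for target in call.converted_to:
                    ecto[target] = ecto.get(target, 0.0) + share
            else:
                endo[s] = comp.expected[s] * reduction_retention
        elif call.status == "expanded":
            if not any(s in c.converted_to for c in delta.calls.values()):
                ecto[s] += comp.expected[s] * expansion_gain
    bad = [s for s in endo if endo[s] < 0 or ecto[s] < 0]
    if bad:
        raise ValueError(f"negative expected counts after delta for {bad}")
    return endo, ecto


def effective_census(comp: CompositionTable, delta: FateDelta | None = None,
                     expansion_gain: float = DEFAULT_EXPANSION_GAIN,
                     reduction_retention: float = DEFAULT_REDUCTION_RETENTION,
                     conversion_fraction: float = DEFAULT_CONVERSION_FRACTION) -> dict:
    """Expected sensilla count per subtype after applying a fate delta."""
    endo, ecto = _census_components(comp, delta, expansion_gain,
                                    reduction_retention, conversion_fraction)
    return {s: endo[s] + ecto[s] for s in endo}


def _revertible_fates(delta: FateDelta | None, clones: CloneModel | None) -> set:
    """Expanded fates whose ectopic conversion needs the clone's missing factor."""
    if delta is None or clones is None:
        return set()
    factor = _SECONDARY_FACTORS[clones.secondary]
    fates = expected_fate_map()
    from .ring_segmentation import wild_type_reference

    ring_codes = {ring.label: ring.code.on_set for ring in wild_type_reference().rings}
    out = set()
    for s, call in delta.calls.items():
        if call.status != "expanded":
            continue
        ring = fates.ring_of(s)
        if ring is not None and factor in ring_codes.get(ring, frozenset()):
            out.add(s)
    return out


def expected_class_mean(comp: CompositionTable, orn_class: str,
                        delta: FateDelta | None = None,
                        clones: CloneModel | None = None,
                        expansion_gain: float = DEFAULT_EXPANSION_GAIN) -> float:
    """Closed-form expectation of a class count under the simulation model."""
    endo, ecto = _census_components(comp, delta, expansion_gain,
                                    DEFAULT_REDUCTION_RETENTION,
                                    DEFAULT_CONVERSION_FRACTION)
    revertible = _revertible_fates(delta, clones)
    f = clones.clone_fraction if clones is not None else 0.0
    mean = 0.0
    for s in comp.sensilla_of_class(orn_class):
        keep = (1.0 - f) if s in revertible else 1.0
        mean += endo[s] + ecto[s] * keep
    return mean


def simulate_antennae(comp: CompositionTable, delta: FateDelta | None,
                      n: int, seed: int, clones: CloneModel | None = None,
                      expansion_gain: float = DEFAULT_EXPANSION_GAIN,
                      reduction_retention: float = DEFAULT_REDUCTION_RETENTION,
                      conversion_fraction: float = DEFAULT_CONVERSION_FRACTION) -> list:
    """Draw n antennae of Poisson sensilla counts under a genotype.

    Separate deterministic substreams are used for the census draws and the
    clone assignments, so a mosaic with f = 0 reproduces the clone-free
    simulation bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    comp.validate()
    if clones is not None:
        clones.validate()
    endo, ecto = _census_components(comp, delta, expansion_gain,
                                    reduction_retention, conversion_fraction)
    revertible = _revertible_fates(delta, clones)

    ss = np.random.SeedSequence(seed)
    rng_counts, rng_clones = (np.random.default_rng(s) for s in ss.spawn(2))
    genotype = delta.genotype if delta is not None else "wild_type"
    if clones is not None:
        genotype += f"+clones({clones.secondary},f={clones.clone_fraction})"

    subtypes = sorted(comp.expected)
    samples = []
    for i in range(n):
        sensilla_counts = {}
        clone_total = 0
        grand_total = 0
        for s in subtypes:
            n_endo = int(rng_counts.poisson(endo[s]))
            n_ecto = int(rng_counts.poisson(ecto[s])) if ecto[s] > 0 else 0
            surviving = n_endo + n_ecto
            if clones is not None:
                c_endo = int(rng_clones.binomial(n_endo, clones.clone_fraction))
                c_ecto = int(rng_clones.binomial(n_ecto, clones.clone_fraction))
                clone_total += c_endo + c_ecto
                if s in revertible:
                    surviving -= c_ecto  # clone-resident ectopic sensilla revert
            grand_total += n_endo + n_ecto
            sensilla_counts[s] = surviving
        counts = {}
        for s in subtypes:
            for cls in comp.classes[s]:
                counts[cls] = counts.get(cls, 0) + sensilla_counts[s]
        samples.append(AntennaSample(
            genotype=genotype, counts=counts, sensilla_counts=sensilla_counts,
            clone_sensilla=clone_total, total_sensilla=grand_total, seed=seed,
        ))
    return samples


def class_counts(samples, orn_class: str) -> np.ndarray:
    """Order-preserving vector of one class's counts across antennae."""
    out = []
    for sample in samples:
        if orn_class not in sample.counts:
            raise KeyError(f"unknown ORN class {orn_class!r}")
        out.append(sample.counts[orn_class])
    return np.asarray(out, dtype=int)


def samples_to_frame(samples) -> pd.DataFrame:
    """Long-format table (antenna_id, class, count) for serialization."""
    rows = []
    for i, sample in enumerate(samples):
        for cls, count in sorted(sample.counts.items()):
            rows.append({"antenna_id": i, "genotype": sample.genotype,
                         "class": cls, "count": count})
    return pd.DataFrame(rows)
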