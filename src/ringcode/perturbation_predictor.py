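"""Qualitative fate and receptor-direction predictions for network perturbations.

Two routes produce a :class:`FateDelta`:

*   Territorial changes.  A perturbed, reference-labelled ring map is
    compared with the wild type per label: sensilla fates of labels that
    gained radial extent expand, fates of labels that lost extent or
    disappeared are reduced or lost, and a disappeared domain's fates are
    converted to the fates of the label(s) that absorbed its territory.

*   Within-ring Bab-level conversions.  Bab is graded, and distinct fates in
    one ring require different Bab levels.  A hypomorphic reduction (kappa)
    demotes each ring's level class by one step; fates requiring more Bab
    than the demoted class convert to their lowest-requirement siblings in
    the same ring, which expand in compensation.  R(6) fates (at4, ac2)
    tolerate a wide Bab range and are exempt.

Receptor direction calls then propagate sensilla status to the olfactory
receptor genes housed in each sensilla: every OR of an expanded sensilla is
called up, of a reduced/lost sensilla down, otherwise unchanged.  Calls are
purely qualitative -- the underlying evidence (qPCR bars, reporter counts)
supports directions, not fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .disc_model import FACTORS, BabClass, DEFAULT_BAB_PROFILE
from .fate_mapping import FateMap, ReporterTable, _data_path
from .ring_segmentation import RingMap, diff_ringmaps

__all__ = [
    "FateCall",
    "FateDelta",
    "BabThresholdTable",
    "ORDirections",
    "default_bab_thresholds",
    "predict_fate_deltas",
    "apply_bab_conversions",
    "or_direction_calls",
    "concordance",
    "load_rn_sign_table",
    "rn_sign_reference",
]


@dataclass(frozen=True)
class FateCall:
    status: str  # expanded | reduced | lost | unchanged
    provenance: str = ""
    converted_to: tuple = ()  # within-ring conversion targets only


@dataclass
class FateDelta:
    """Per-sensilla qualitative change under one perturbation."""

    genotype: str
    calls: dict  # sensilla -> FateCall
    ring_deltas: tuple = ()

    def status(self, sensilla: str) -> str:
        return self.calls[sensilla].status

    def of_status(self, status: str) -> set:
        return {s for s, c in self.calls.items() if c.status == status}

    def is_empty(self) -> bool:
        return all(c.status == "unchanged" for c in self.calls.values())

    def to_tsv(self, path) -> None:
        rows = [
            {"sensilla": s, "status": c.status,
             "converted_to": ",".join(c.converted_to), "provenance": c.provenance}
            for s, c in sorted(self.calls.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _overlap(a: tuple, b: tuple) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def predict_fate_deltas(wt_rings: RingMap, pert_rings: RingMap, fates: FateMap) -> FateDelta:
    """Translate a labelled perturbed ring map into per-sensilla fate calls."""
    if any(ring.label is None for ring in pert_rings.rings):
        raise ValueError("perturbed ring map must be classified before prediction")
    deltas = diff_ringmaps(wt_rings, pert_rings)
    by_ring = fates.by_ring()

    status_map = {
        "expanded": "expanded",
        "appeared": "expanded",
        "contracted": "reduced",
        "disappeared": "lost",
        "unchanged": "unchanged",
    }
    calls = {}
    for d in deltas:
        sensillae = by_ring.get(d.label, set())
        prov = f"{d.label} {d.change}"
        if d.flags:
            prov += f" [{';'.join(d.flags)}]"
        if d.change == "disappeared":
            # which labels absorbed this territory?
            absorbers = set()
            for wt_ring in wt_rings.by_label(d.label):
                for new_ring in pert_rings.rings:
                    if new_ring.label != d.label and _overlap(wt_ring.extent, new_ring.extent) > 1e-9:
                        absorbers.add(new_ring.label)
            if absorbers:
                prov += "; territory absorbed by " + ",".join(sorted(absorbers))
        for s in sensillae:
            calls[s] = FateCall(status=status_map[d.change], provenance=prov)

    genotype = "+".join(pert_rings.provenance) or "wild_type"
    return FateDelta(genotype=genotype, calls=calls, ring_deltas=tuple(deltas))


@dataclass
class BabThresholdTable:
    """Required Bab level class per fate, grouped by ring.

    ``required`` maps each fate to a :class:`BabClass` (donor fates carry
    the ring's wild-type class; the default low-requirement fates carry
    ``absent``) or to None for fates the hypomorph analysis leaves
    unconstrained ("unchanged" class).  ``wide_tolerance`` lists rings whose
    fates are specified over a wide Bab range and never convert.
    """

    ring_of: dict  # fate -> ring label
    required: dict  # fate -> BabClass | None
    ring_class: dict  # ring label -> wild-type BabClass
    wide_tolerance: frozenset = frozenset()

    def validate(self, fates: FateMap) -> None:
        seen = set()
        for fate in self.required:
            if fate in seen:
                raise ValueError(f"fate {fate} appears more than once")
            seen.add(fate)
        for s in fates.assignments:
            if s not in self.required:
                raise ValueError(f"fate missing from threshold table: {s}")


def default_bab_thresholds(fates: FateMap | None = None) -> BabThresholdTable:
    """Requirements matching the hypomorph observations per ring.

    Donors (require the ring's full wild-type level): ai1 in R(3), at3 in
    R(4), ac1 in R(5), ab2 and ab6 in R(7).  Default fates (adopted when Bab
    falls short): ab7, at1, ab5, ac4, at2.  R(6) is wide-tolerance; R(1) and
    R(2) fates do not depend on Bab; ab4/ab8/ac3 are unconstrained.
    """
    from .fate_mapping import expected_fate_map

    fates = fates or expected_fate_map()
    ring_of = {s: a.ring for s, a in fates.assignments.items()}
    ring_class = {lab: DEFAULT_BAB_PROFILE[lab] for lab in DEFAULT_BAB_PROFILE}
    required: dict = {}
    donors = {"ai1": "R(3)", "at3": "R(4)", "ac1": "R(5)", "ab2": "R(7)", "ab6": "R(7)"}
    defaults = {"ab7", "at1", "ab5", "ac4", "at2"}
    for fate, ring in ring_of.items():
        if fate in donors:
            required[fate] = ring_class[ring]
        elif fate in defaults:
            required[fate] = BabClass.absent
        else:
            required[fate] = None  # unconstrained / Bab-independent
    return BabThresholdTable(
        ring_of=ring_of,
        required=required,
        ring_class=ring_class,
        wide_tolerance=frozenset({"R(6)"}),
    )


def apply_bab_conversions(
    fates: FateMap,
    kappa: float,
    thresholds: BabThresholdTable | None = None,
    kappa_cutoff: float = 0.8,
) -> FateDelta:
    """Within-ring fate conversions under a Bab hypomorph of strength kappa.

    kappa in (0, 1]; below ``kappa_cutoff`` every ring's Bab class is
    demoted one step.  Donor fates (required class above the demoted class)
    are reduced and convert to the lowest-requirement siblings of the same
    ring, which expand; rings flagged wide-tolerance are untouched.
    """
    if not (0 < kappa <= 1):
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    thresholds = thresholds or default_bab_thresholds(fates)
    thresholds.validate(fates)

    calls = {s: FateCall("unchanged", provenance="no demotion")
             for s in fates.assignments}
    if kappa >= kappa_cutoff:
        return FateDelta(genotype=f"bab_hypomorph(kappa={kappa})", calls=calls)

    by_ring: dict[str, list] = {}
    for fate, ring in thresholds.ring_of.items():
        by_ring.setdefault(ring, []).append(fate)

    for ring, members in by_ring.items():
        if ring in thresholds.wide_tolerance:
            for f in members:
                calls[f] = FateCall("unchanged", provenance=f"{ring} wide Bab tolerance")
            continue
        demoted = BabClass(max(int(thresholds.ring_class[ring]) - 1, 0))
        classed = [f for f in members if thresholds.required[f] is not None]
        donors = [f for f in classed if thresholds.required[f] > demoted]
        if not donors:
            continue
        non_donors = [f for f in classed if f not in donors]
        if non_donors:
            low = min(thresholds.required[f] for f in non_donors)
            recipients = tuple(sorted(f for f in non_donors
                                      if thresholds.required[f] == low))
        else:
            recipients = ()
        for f in donors:
            calls[f] = FateCall(
                "reduced",
                provenance=f"{ring} Bab demoted to {demoted.name}; requires "
                           f"{thresholds.required[f].name}",
                converted_to=recipients,
            )
        for f in recipients:
            calls[f] = FateCall(
                "expanded",
                provenance=f"{ring} gains converted precursors from "
                           + ",".join(sorted(donors)),
            )
    return FateDelta(genotype=f"bab_hypomorph(kappa={kappa})", calls=calls)


@dataclass
class ORDirections:
    """Per-receptor-gene qualitative direction, derived from a FateDelta.

    ``conflicts`` records genes housed in several sensilla subtypes whose
    parent sensilla disagree (only IR75d can trigger this); such genes carry
    no direction call.
    """

    directions: dict  # gene -> up | down | unchanged
    derived_from: FateDelta | None = None
    conflicts: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [{"gene": g, "direction": d} for g, d in sorted(self.directions.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_STATUS_TO_DIRECTION = {
    "expanded": "up", "reduced": "down", "lost": "down", "unchanged": "unchanged",
}


def or_direction_calls(delta: FateDelta, table: ReporterTable) -> ORDirections:
    """Propagate sensilla fate status to olfactory receptor genes.

    Every OR gene inherits the direction of the sensilla housing it
    (expanded -> up, reduced/lost -> down).  Genes appearing in several
    sensilla (IR75d) whose sensilla disagree are reported as conflicts.
    """
    genes_by_sensilla = table.genes_for_sensilla()
    for s in genes_by_sensilla:
        if s not in delta.calls:
            raise ValueError(f"fate delta has no call for sensilla {s}")

    votes: dict[str, set] = {}
    for s, genes in genes_by_sensilla.items():
        direction = _STATUS_TO_DIRECTION[delta.calls[s].status]
        for g in genes:
            votes.setdefault(g, set()).add(direction)
    directions, conflicts = {}, {}
    for g, vote in votes.items():
        if len(vote) == 1:
            directions[g] = next(iter(vote))
        else:
            conflicts[g] = tuple(sorted(vote))
    return ORDirections(directions=directions, derived_from=delta, conflicts=conflicts)


def concordance(calls: ORDirections, reference: dict) -> tuple:
    """Fraction of overlapping genes whose direction matches the reference.

    ``unchanged`` matches only ``unchanged``.  Returns (fraction, per-gene
    agreement list of (gene, called, reference, agree)).
    """
    overlap = sorted(set(calls.directions) & set(reference))
    if not overlap:
        raise ValueError("no overlap between called and reference gene sets")
    agreement = []
    hits = 0
    for g in overlap:
        agree = calls.directions[g] == reference[g]
        hits += agree
        agreement.append((g, calls.directions[g], reference[g], agree))
    return hits / len(overlap), agreement


def load_rn_sign_table() -> pd.DataFrame:
    """Bundled rn-mutant receptor direction table with per-entry provenance.

    ``confidence`` separates directions supported by explicit statements
    (``text``) from those inferred only from figure shading or indirect
    remarks (``figure_only``); the latter are excluded from reference use
    by default.
    """
    return pd.read_csv(_data_path("rn_sign_table.tsv"), sep="\t")


def rn_sign_reference(include_figure_only: bool = False) -> dict:
    df = load_rn_sign_table()
    if not include_figure_only:
        df = df[df["confidence"] == "text"]
    return dict(zip(df["gene"], df["direction"]))
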