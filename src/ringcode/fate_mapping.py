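"""Mapping sensilla subtype fates onto the concentric ring domains.

Each adult sensilla subtype houses 1-4 olfactory receptor neuron (ORN)
classes.  GAL4 reporter lines for the five prepatterning factors label
specific ORN classes (read out through their target glomeruli), giving every
sensilla subtype an aggregated reporter-positivity code over
{Ap, Bar, Bab, Rn, Dac}.  Matching these codes against the ring codes of the
third-instar disc assigns each subtype to the ring its precursor came from.

Aggregation applies a small set of documented override rules where reporter
expression in adult ORNs conflicts with the larval disc pattern (late or
artifactual reporter expression); every override carries its provenance
quote.  Assignment then proceeds by superset matching: reporter expression
in the adult may miss factors that act only transiently in the precursor, so
a ring is a candidate when its code contains the sensilla code, subject to
two hard constraints (rings expressing Rn or Dac only admit rn-/dac-positive
sensilla, because both reporters faithfully mark their lineages).  Among
candidates, the ring with the fewest surplus factors wins; unresolved ties
and codes with no positive factor are reported as ambiguous rather than
silently resolved.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .disc_model import FACTORS
from .ring_segmentation import RingMap

__all__ = [
    "ReporterTable",
    "OverrideRule",
    "SensillaCode",
    "Assignment",
    "FateMap",
    "load_table1",
    "default_overrides",
    "aggregate_sensilla_codes",
    "assign_rings",
    "expected_fate_map",
]

_CALLS = ("+", "w", "-")
_FACTOR_COLS = {"ap": "Ap", "bar": "Bar", "bab": "Bab", "rn": "Rn", "dac": "Dac"}

#: the one ORN class found in more than one sensilla subtype
MULTI_SENSILLA_CLASS = "IR75d"


def _data_path(name: str):
    return importlib.resources.files("ringcode.data") / name


@dataclass
class ReporterTable:
    """Reporter-expression calls per ORN class (rows) and factor (columns).

    ``frame`` columns: sensilla, orn_class, receptors (comma-joined OR/IR/GR
    gene names), glomerulus, and one three-valued call column per factor
    (``+`` positive, ``w`` weak, ``-`` negative).
    """

    frame: pd.DataFrame

    def validate(self) -> None:
        required = {"sensilla", "orn_class", "receptors", "glomerulus", *_FACTOR_COLS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"reporter table missing columns: {sorted(missing)}")
        for col in _FACTOR_COLS:
            bad = set(self.frame[col]) - set(_CALLS)
            if bad:
                raise ValueError(f"invalid calls in column {col}: {sorted(bad)}")
        # every ORN class belongs to one sensilla subtype, except IR75d
        counts = self.frame.groupby("orn_class")["sensilla"].nunique()
        offenders = counts[(counts > 1) & (counts.index != MULTI_SENSILLA_CLASS)]
        if len(offenders):
            raise ValueError(
                f"ORN classes in multiple sensilla besides {MULTI_SENSILLA_CLASS}: "
                f"{sorted(offenders.index)}"
            )

    def sensilla(self) -> list:
        return list(dict.fromkeys(self.frame["sensilla"]))

    def genes_for_sensilla(self) -> dict:
        """sensilla -> sorted list of receptor genes of its ORN classes."""
        out: dict[str, list] = {}
        for _, row in self.frame.iterrows():
            genes = [g for g in str(row["receptors"]).split(",") if g and g != "-"]
            out.setdefault(row["sensilla"], []).extend(genes)
        return {s: sorted(dict.fromkeys(g)) for s, g in out.items()}

    def sensilla_for_gene(self, gene: str) -> str:
        for s, genes in self.genes_for_sensilla().items():
            if gene in genes:
                return s
        raise KeyError(f"receptor gene {gene!r} not in reporter table")


def load_table1() -> ReporterTable:
    """The bundled ORN-class x reporter table (19 antennal sensilla subtypes)."""
    frame = pd.read_csv(_data_path("table1.tsv"), sep="\t", dtype=str)
    table = ReporterTable(frame=frame)
    table.validate()
    return table


@dataclass(frozen=True)
class OverrideRule:
    """A documented correction applied during aggregation.

    ``target`` names either a sensilla subtype or an ORN class; ``action``
    is ``drop_call`` (remove the factor from the aggregate), ``keep_call``
    (explicitly retain a call that might look artifactual) or
    ``flag_ambiguous`` (mark the sensilla unresolved, optionally annotating
    an alternate ring).  Every rule carries its verbatim provenance quote.
    """

    name: str
    target: str
    factor: str | None
    action: str
    provenance: str
    alternate_ring: str | None = None


def default_overrides() -> list:
    """The override set used for the reference fate map."""
    o1 = "attribute this discrepancy to either an artifact of the bab reporter or late expression of Bab"
    return [
        OverrideRule("O1a", "ab1", "Bab", "drop_call", o1),
        OverrideRule("O1b", "ab9", "Bab", "drop_call", o1),
        OverrideRule("O1c", "ab3", "Bab", "drop_call", o1),
        OverrideRule(
            "O2", MULTI_SENSILLA_CLASS, "Dac", "drop_call",
            "cannot distinguish whether this is due to a developmentally related "
            "event unique to this ORN class or an artifact of the reporter expression",
        ),
        OverrideRule(
            "O3", MULTI_SENSILLA_CLASS, "Bar", "keep_call",
            "ac2, which is bab-, Bar-positive, and ap-, rn-negative",
        ),
        OverrideRule(
            "O4", "ab3", None, "flag_ambiguous",
            "unable to fully resolve the origin of ab3 sensilla",
            alternate_ring="R(7)",
        ),
    ]


@dataclass(frozen=True)
class SensillaCode:
    """Aggregated prepatterning code of one sensilla subtype."""

    sensilla: str
    on_set: frozenset
    weak_set: frozenset  # factors supported only by weak ("+/-") calls
    applied_overrides: tuple = ()
    ambiguous: bool = False
    alternate_ring: str | None = None

    def __post_init__(self):
        if not self.weak_set <= self.on_set:
            raise ValueError("weak_set must be a subset of on_set")


def aggregate_sensilla_codes(table: ReporterTable, overrides=None) -> dict:
    """Aggregate per-class reporter calls into per-sensilla codes.

    A sensilla is positive for a factor iff ANY constituent ORN class is
    ``+`` or weak for it, after overrides.  Weak-only factors are kept in
    ``weak_set`` for reporting (weak counts as positive for assignment).
    """
    table.validate()
    overrides = list(default_overrides() if overrides is None else overrides)

    known_sensilla = set(table.sensilla())
    known_classes = set(table.frame["orn_class"])
    for rule in overrides:
        if rule.target not in known_sensilla | known_classes:
            raise ValueError(f"override {rule.name} targets unknown sensilla/class {rule.target!r}")
        if rule.factor is not None and rule.factor not in FACTORS:
            raise ValueError(f"override {rule.name} names unknown factor {rule.factor!r}")

    class_drops = {
        (r.target, r.factor) for r in overrides
        if r.action == "drop_call" and r.target in known_classes
    }
    sensilla_drops = {
        (r.target, r.factor) for r in overrides
        if r.action == "drop_call" and r.target in known_sensilla
    }
    rule_by_key = {}
    for r in overrides:
        if r.factor is not None:
            rule_by_key[(r.target, r.factor)] = r

    codes = {}
    for sensilla in table.sensilla():
        rows = table.frame[table.frame["sensilla"] == sensilla]
        strong, weak = set(), set()
        applied = []
        for col, factor in _FACTOR_COLS.items():
            for _, row in rows.iterrows():
                call = row[col]
                if call == "-":
                    continue
                if (row["orn_class"], factor) in class_drops:
                    applied.append(rule_by_key[(row["orn_class"], factor)].name)
                    continue
                (strong if call == "+" else weak).add(factor)
        for factor in list(strong | weak):
            if (sensilla, factor) in sensilla_drops:
                strong.discard(factor)
                weak.discard(factor)
                applied.append(rule_by_key[(sensilla, factor)].name)
        ambiguous = False
        alternate = None
        for r in overrides:
            if r.action == "flag_ambiguous" and r.target == sensilla:
                ambiguous = True
                alternate = r.alternate_ring
                applied.append(r.name)
        on_set = frozenset(strong | weak)
        codes[sensilla] = SensillaCode(
            sensilla=sensilla,
            on_set=on_set,
            weak_set=frozenset(weak - strong),
            applied_overrides=tuple(dict.fromkeys(applied)),
            ambiguous=ambiguous,
            alternate_ring=alternate,
        )
    return codes


@dataclass(frozen=True)
class Assignment:
    sensilla: str
    ring: str | None
    basis: str  # exact | subset | override | ambiguous | unassigned
    extras: int | None = None
    candidates: tuple = ()
    alternate_ring: str | None = None


@dataclass
class FateMap:
    """ring label -> sensilla subtypes, with per-sensilla assignment basis."""

    assignments: dict  # sensilla -> Assignment

    def by_ring(self) -> dict:
        out: dict[str, set] = {}
        for a in self.assignments.values():
            if a.ring is not None:
                out.setdefault(a.ring, set()).add(a.sensilla)
        return out

    def ring_of(self, sensilla: str) -> str | None:
        return self.assignments[sensilla].ring

    def sensilla_in(self, ring: str) -> set:
        return self.by_ring().get(ring, set())

    def unassigned(self) -> set:
        return {s for s, a in self.assignments.items() if a.ring is None}

    def to_tsv(self, path) -> None:
        rows = [
            {"ring": a.ring or "", "sensilla": s, "basis": a.basis,
             "alternate": a.alternate_ring or ""}
            for s, a in sorted(self.assignments.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def __eq__(self, other):
        """Maps are equal when every sensilla has the same ring, basis and
        alternate-ring annotation (candidate bookkeeping is not compared)."""
        if not isinstance(other, FateMap):
            return NotImplemented
        key = lambda m: {
            s: (a.ring, a.basis, a.alternate_ring) for s, a in m.assignments.items()
        }
        return key(self) == key(other)


def assign_rings(codes: dict, ring_reference: RingMap) -> FateMap:
    """Deterministic ring assignment for aggregated sensilla codes.

    1.  Hard constraints: a ring whose code contains Rn (resp. Dac) is
        admissible only for rn- (resp. dac-) positive sensilla.
    2.  Candidates are admissible rings whose code is a superset of the
        sensilla code (factors may be missing from the adult readout).
    3.  The candidate minimising the number of surplus ring factors wins.
    4.  Unresolved ties, and codes with no positive factor at all, yield no
        primary ring and basis ``ambiguous``; codes with no candidate are
        reported unassigned.
    """
    ref_rings = [(ring.label, set(ring.code.on_set)) for ring in ring_reference.rings]
    if any(lab is None for lab, _ in ref_rings):
        raise ValueError("ring reference must be labelled")

    assignments = {}
    for sensilla, code in codes.items():
        on = set(code.on_set)
        admissible = [
            (lab, ring_on) for lab, ring_on in ref_rings
            if ("Rn" not in ring_on or "Rn" in on) and ("Dac" not in ring_on or "Dac" in on)
        ]
        candidates = [(lab, len(ring_on - on), ring_on) for lab, ring_on in admissible
                      if ring_on >= on]
        if not on:
            assignments[sensilla] = Assignment(
                sensilla, None, "ambiguous",
                candidates=tuple(lab for lab, _, _ in candidates),
                alternate_ring=code.alternate_ring,
            )
            continue
        if not candidates:
            assignments[sensilla] = Assignment(
                sensilla, None, "unassigned", candidates=(),
                alternate_ring=code.alternate_ring,
            )
            continue
        best_extras = min(extras for _, extras, _ in candidates)
        winners = [(lab, ring_on) for lab, extras, ring_on in candidates
                   if extras == best_extras]
        if len(winners) > 1:
            assignments[sensilla] = Assignment(
                sensilla, None, "ambiguous",
                extras=best_extras,
                candidates=tuple(lab for lab, _ in winners),
                alternate_ring=code.alternate_ring,
            )
            continue
        label, ring_on = winners[0]
        if code.ambiguous:
            basis = "ambiguous"
        elif any(name.startswith("O") and not name.startswith("O3")
                 for name in code.applied_overrides):
            basis = "override"
        elif ring_on == on:
            basis = "exact"
        else:
            basis = "subset"
        assignments[sensilla] = Assignment(
            sensilla, label, basis, extras=best_extras,
            candidates=tuple(lab for lab, _ in winners),
            alternate_ring=code.alternate_ring,
        )
    return FateMap(assignments=assignments)


#: Reference fate map: ring -> sensilla, with assignment basis per sensilla.
_EXPECTED = {
    "R(1)": {"ab1": "override", "ab3": "ambiguous", "ab9": "override"},
    "R(2)": {"ab10": "exact"},
    "R(3)": {"ab7": "exact", "ai1": "exact"},
    "R(4)": {"at1": "exact", "at3": "exact", "ab5": "exact"},
    "R(5)": {"ac1": "override", "ac4": "override"},
    "R(6)": {"at4": "exact", "ac2": "override"},
    "R(7)": {"at2": "exact", "ab2": "subset", "ab4": "exact",
             "ab6": "subset", "ab8": "subset", "ac3": "subset"},
}


def expected_fate_map() -> FateMap:
    """The golden ring -> sensilla fate map used by the validation suite.

    19 antennal sensilla subtypes over seven rings; ab3 is flagged ambiguous
    with alternate ring R(7) (its origin could not be fully resolved).
    """
    assignments = {}
    for ring, members in _EXPECTED.items():
        for sensilla, basis in members.items():
            assignments[sensilla] = Assignment(
                sensilla, ring, basis,
                alternate_ring="R(7)" if sensilla == "ab3" else None,
            )
    return FateMap(assignments=assignments)
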