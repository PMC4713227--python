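"""Segmentation of a disc state into labelled concentric ring domains.

A ring is a maximal radial run of positions sharing the same factor ON-set.
The graded Bab level class does not split rings -- rings are defined by
factor combinations; the Bab level sub-specifies fates within a ring -- but
each ring records its modal level class.  Rings are ordered periphery ->
centre and, in the wild type, labelled R(1) (outermost) to R(7) (centre).

Perturbed ring maps are labelled against the wild-type reference by minimal
code distance.  The distance is a Hamming distance over the five factors in
which Ap and Bar form one equivalence class (the two are partially redundant
for ring identity): a mismatch on Ap or on Bar costs 1/2, so the pair
jointly contributes at most 1.  Under this metric the rn-mutant ring code
{Bar, Bab} sits at distance 1/2 from R(6) (missing Ap) and distance 2 from
R(4), recovering the interpretation that R(6) expands outward in rn mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .disc_model import FACTORS, BabClass, DiscState, ThresholdParams, default_params, simulate_disc

__all__ = [
    "RingCode",
    "Ring",
    "RingMap",
    "DomainDelta",
    "segment_rings",
    "classify_rings",
    "diff_ringmaps",
    "locate_central_fold",
    "wild_type_reference",
    "code_distance",
]

#: tie-break priority for classification (highest first); Ap and Bar are one class
_PRIORITY = ("Rn", "Dac", "ApBar", "Bab")


@dataclass(frozen=True)
class RingCode:
    """Combinatorial code of one ring: factor ON-set plus Bab level class."""

    on_set: frozenset
    bab_class: BabClass = BabClass.absent

    def __post_init__(self):
        unknown = self.on_set - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors in code: {sorted(unknown)}")
        if ("Bab" in self.on_set) != (self.bab_class != BabClass.absent):
            raise ValueError(
                f"Bab in on_set iff bab_class != absent violated: "
                f"{sorted(self.on_set)} / {self.bab_class.name}"
            )

    def __str__(self):
        names = [f for f in FACTORS if f in self.on_set]
        if "Bab" in self.on_set:
            names[names.index("Bab")] = f"Bab/{self.bab_class.name}"
        return "{" + ",".join(names) + "}"


def code_distance(a: RingCode, b: RingCode) -> float:
    """Hamming distance with Ap/Bar as one equivalence class (1/2 each)."""
    d = 0.0
    for f in ("Dac", "Rn", "Bab"):
        d += (f in a.on_set) != (f in b.on_set)
    for f in ("Ap", "Bar"):
        d += 0.5 * ((f in a.on_set) != (f in b.on_set))
    return d


def _priority_mismatch(a: RingCode, b: RingCode) -> tuple:
    """Per-priority-level mismatch vector used to break distance ties."""
    out = []
    for level in _PRIORITY:
        if level == "ApBar":
            m = 0.5 * (("Ap" in a.on_set) != ("Ap" in b.on_set))
            m += 0.5 * (("Bar" in a.on_set) != ("Bar" in b.on_set))
        else:
            m = float((level in a.on_set) != (level in b.on_set))
        out.append(m)
    return tuple(out)


@dataclass(frozen=True)
class Ring:
    """One constant-code domain with extent [inner, outer) on the radial axis."""

    label: str | None
    code: RingCode
    extent: tuple  # (inner, outer), half-open in r
    distance: float = 0.0
    tie: bool = False
    flags: tuple = ()

    @property
    def width(self) -> float:
        return self.extent[1] - self.extent[0]


@dataclass
class RingMap:
    """Ordered (periphery -> centre) list of rings tiling [0, 1]."""

    rings: list
    central_fold: float | None = None
    provenance: tuple = ()

    def __iter__(self):
        return iter(self.rings)

    def __len__(self):
        return len(self.rings)

    def labels(self) -> list:
        return [ring.label for ring in self.rings]

    def codes(self) -> list:
        return [ring.code for ring in self.rings]

    def by_label(self, label: str) -> list:
        return [ring for ring in self.rings if ring.label == label]

    def total_extent(self, label: str) -> float:
        return float(sum(ring.width for ring in self.by_label(label)))

    def validate(self) -> None:
        if not self.rings:
            raise ValueError("empty ring map")
        outer = 1.0
        for ring in self.rings:
            lo, hi = ring.extent
            if not np.isclose(hi, outer):
                raise ValueError(f"extents do not tile [0,1]: gap at {hi} != {outer}")
            outer = lo
        if not np.isclose(outer, 0.0):
            raise ValueError(f"extents do not reach the centre: {outer}")
        for a, b in zip(self.rings, self.rings[1:]):
            if a.code.on_set == b.code.on_set:
                raise ValueError("adjacent rings share an on_set; segmentation not maximal")

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for ring in self.rings:
            rows.append({
                "label": ring.label or "",
                "on_set": ",".join(f for f in FACTORS if f in ring.code.on_set),
                "bab_class": ring.code.bab_class.name,
                "inner": ring.extent[0],
                "outer": ring.extent[1],
                "distance": ring.distance,
                "tie": int(ring.tie),
                "flags": ";".join(ring.flags),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DomainDelta:
    label: str
    change: str  # expanded | contracted | unchanged | appeared | disappeared
    old_extent: float
    new_extent: float
    flags: tuple = ()


def segment_rings(state: DiscState) -> RingMap:
    """Partition the disc into maximal constant-on_set runs, periphery first.

    The resulting partition is the unique coarsest one: any two adjacent
    positions with the same ON-set land in the same ring, and adjacent rings
    always differ.  Each ring records the modal Bab level class over its
    positions (ties resolved toward the higher class), and a ``dac_reduced``
    flag when any position in the run carries one.
    """
    n = len(state.positions)
    order = np.argsort(state.positions)[::-1]  # periphery -> centre
    on = np.column_stack([state.factor_on(f) for f in FACTORS])[order]
    bab_class = state.bab_class[order]
    dac_red = state.dac_reduced[order]
    r = state.positions[order]

    # half-open extents with boundaries at midpoints between sample positions
    edges_outer = np.empty(n)
    edges_inner = np.empty(n)
    edges_outer[0] = 1.0
    mids = (r[:-1] + r[1:]) / 2.0
    edges_outer[1:] = mids
    edges_inner[:-1] = mids
    edges_inner[-1] = 0.0

    rings = []
    start = 0
    for i in range(1, n + 1):
        if i == n or not np.array_equal(on[i], on[start]):
            members = slice(start, i)
            on_set = frozenset(f for f, flag in zip(FACTORS, on[start]) if flag)
            if "Bab" in on_set:
                classes = bab_class[members]
                vals, counts = np.unique(classes, return_counts=True)
                modal = int(vals[counts == counts.max()].max())
            else:
                modal = 0
            flags = ("dac_reduced",) if dac_red[members].any() else ()
            rings.append(Ring(
                label=None,
                code=RingCode(on_set=on_set, bab_class=BabClass(modal)),
                extent=(float(edges_inner[i - 1]), float(edges_outer[start])),
                flags=flags,
            ))
            start = i

    rmap = RingMap(
        rings=rings,
        central_fold=state.central_fold,
        provenance=tuple(p.describe() for p in state.perturbations),
    )
    rmap.validate()
    return rmap


def wild_type_reference(params: ThresholdParams | None = None) -> RingMap:
    """Wild-type seven-ring map with canonical labels R(1)..R(7)."""
    params = params or default_params()
    rmap = segment_rings(simulate_disc(params, []))
    if len(rmap) != 7:
        raise ValueError(
            f"parameters do not produce the seven-ring reference (got {len(rmap)})"
        )
    rmap.rings = [replace(ring, label=f"R({i + 1})") for i, ring in enumerate(rmap.rings)]
    return rmap


def classify_rings(rmap: RingMap, reference: RingMap) -> RingMap:
    """Label each ring with the reference label of minimal code distance.

    Ties at the minimal distance are broken by factor priority
    Rn > Dac > Bar/Ap > Bab (prefer the reference ring that agrees on the
    higher-priority factor), then by the outermost reference ring; tied
    rings are flagged rather than silently resolved.
    """
    if not rmap.rings:
        raise ValueError("cannot classify an empty ring map")
    if any(ring.label is None for ring in reference.rings):
        raise ValueError("reference map must be fully labelled")

    labelled = []
    for ring in rmap.rings:
        dists = [(code_distance(ring.code, ref.code), ref) for ref in reference.rings]
        dmin = min(d for d, _ in dists)
        candidates = [ref for d, ref in dists if d == dmin]
        tie = len(candidates) > 1
        best = min(
            candidates,
            key=lambda ref: (_priority_mismatch(ring.code, ref.code),
                             reference.rings.index(ref)),
        )
        labelled.append(replace(ring, label=best.label, distance=dmin, tie=tie))
    return RingMap(rings=labelled, central_fold=rmap.central_fold,
                   provenance=rmap.provenance)


def diff_ringmaps(a: RingMap, b: RingMap, atol: float = 1e-9) -> list:
    """Per-label extent comparison between two labelled ring maps.

    ``a`` is typically the wild-type reference.  Every label of ``a`` is
    accounted for exactly once; labels present only in ``b`` are reported as
    ``appeared``.  A label expanded iff its total extent is strictly larger
    (beyond ``atol``).  Flags carry side observations: ``dac_reduced`` when
    a matching domain has reduced Dac, ``relocated`` when the total extent
    is unchanged but the domain moved, and ``paper_silent`` on an unchanged
    R(7) under rn-null (the source data do not constrain R(7) there).
    """
    labels_a = [lab for lab in a.labels() if lab is not None]
    labels_b = [lab for lab in b.labels() if lab is not None]
    if None in a.labels() or None in b.labels():
        raise ValueError("both maps must be labelled before diffing")
    if not set(labels_b) <= set(labels_a) | set(labels_b):
        raise ValueError("label sets not comparable")

    any_change = False
    deltas = []
    for lab in dict.fromkeys(labels_a):
        old = a.total_extent(lab)
        new = b.total_extent(lab)
        flags = []
        for ring in b.by_label(lab):
            flags.extend(ring.flags)
        if new <= atol:
            change = "disappeared"
        elif new > old + atol:
            change = "expanded"
        elif new < old - atol:
            change = "contracted"
        else:
            change = "unchanged"
            old_pos = sorted(ring.extent for ring in a.by_label(lab))
            new_pos = sorted(ring.extent for ring in b.by_label(lab))
            if not all(
                np.allclose(x, y, atol=1e-6) for x, y in zip(old_pos, new_pos)
            ) or len(old_pos) != len(new_pos):
                flags.append("relocated")
        if change != "unchanged":
            any_change = True
        deltas.append(DomainDelta(lab, change, old, new, tuple(dict.fromkeys(flags))))

    for lab in dict.fromkeys(labels_b):
        if lab not in labels_a:
            deltas.append(DomainDelta(lab, "appeared", 0.0, b.total_extent(lab)))
            any_change = True

    if any_change and "rn:null" in b.provenance:
        deltas = [
            replace(d, flags=d.flags + ("paper_silent",))
            if d.label == "R(7)" and d.change == "unchanged" else d
            for d in deltas
        ]
    return deltas


def locate_central_fold(state: DiscState):
    """Outer boundary of the Ap-ON region, or None when the fold is absent.

    The fold is morphologically absent under Bar overexpression, and
    undefined when Ap is OFF everywhere.  With Ap ON everywhere the fold
    sits at r = 1 (the whole disc is interior).
    """
    for p in state.perturbations:
        if p.gene == "Bar" and p.mode == "force_on_in_domain":
            return None
    if not np.any(state.ap):
        return None
    n = len(state.positions)
    outermost = state.positions[state.ap].max()
    return float(min(outermost + 0.5 / n, 1.0))
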