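"""Threshold-logic model of proximodistal prepatterning in the antennal disc.

The third-instar antennal disc is patterned by an EGF signalling gradient that
is highest at the disc centre and decays outward.  Five transcription factors
-- Dachshund (Dac), Rotund (Rn), Apterous (Ap), BarH1/H2 (Bar) and
Bric-a-brac (Bab) -- read this gradient through cross-regulatory rules and
partition a 1-D radial axis (r = 0 disc centre, r = 1 periphery) into seven
concentric domains, each with a unique combinatorial ON/OFF code.

The network is evaluated as a single acyclic feed-forward pass in the fixed
order E -> Dac -> Ap -> Rn -> Bar -> Bab.  The model is a static snapshot:
no temporal dynamics, no 2-D geometry, no proliferation.

Two morphogen layers are distinguished.  Perturbations of EGFR signalling
(``boost_morphogen``) raise the *effective* gradient read by Ap, Rn and Bar.
Dac and the centremost Bar exclusion zone are evaluated on the *baseline*
gradient: Dac's domain is established before the late-third-instar snapshot
modelled here, and the centremost Bar repressor is an unidentified factor
anchored to disc position rather than to EGFR activity.  This choice
reproduces the constitutively-active-EGFR phenotype (Bar expands until its
domain abuts an intact Dac domain, and the central fold moves outward).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "GENES",
    "MODES",
    "BabClass",
    "ThresholdParams",
    "Perturbation",
    "DiscState",
    "ValidationError",
    "default_params",
    "build_perturbation",
    "simulate_disc",
]

FACTORS = ("Dac", "Rn", "Ap", "Bar", "Bab")
GENES = ("rn", "Bar", "bab", "ap", "dac", "EGFR")
MODES = ("null", "force_on_in_domain", "scale_level", "boost_morphogen")

#: Named driver domains, each a predicate over baseline morphogen level E.
#: ``rn_active`` emulates the rn-GAL4 driver: active wherever the rn promoter
#: would be on in the unperturbed disc.
DOMAINS = ("everywhere", "rn_active", "ap_endogenous", "dac_active")


class ValidationError(ValueError):
    """Raised for malformed parameters or perturbations."""


class BabClass(enum.IntEnum):
    """Ordinal Bab level class; the disc carries a graded, not binary, Bab."""

    absent = 0
    low = 1
    mid = 2
    high = 3


def _demote(c: BabClass) -> BabClass:
    return BabClass(max(c - 1, 0))


# Reference ring labels ordered periphery -> centre.
RING_LABELS = tuple(f"R({i})" for i in range(1, 8))

#: Bab level class per reference ring (periphery -> centre).  Peak near the
#: central fold (R(4)/R(5)), decaying toward both the outermost and the
#: innermost regions.
DEFAULT_BAB_PROFILE = {
    "R(1)": BabClass.absent,
    "R(2)": BabClass.absent,
    "R(3)": BabClass.low,
    "R(4)": BabClass.high,
    "R(5)": BabClass.high,
    "R(6)": BabClass.mid,
    "R(7)": BabClass.low,
}


@dataclass(frozen=True)
class ThresholdParams:
    """Free parameters of the threshold-logic system.

    The published rules are qualitative; thresholds are the artifact's free
    parameters, chosen so the wild-type simulation reproduces the reference
    seven-ring sequence.  All thresholds act on the dimensionless morphogen
    level E(r) = 1 - r.

    Parameters
    ----------
    theta_ap, theta_dac, theta_rn_low, theta_rn_high, theta_bar_center
        Morphogen thresholds; require ``0 < theta_rn_low < theta_rn_high <= 1``
        and ``theta_bar_center > theta_ap > theta_dac``.
    bab_profile
        Bab level class per reference ring label.
    kappa
        Global multiplicative Bab scale in (0, 1]; 1 is wild type.  Values
        below ``kappa_cutoff`` demote every ring's Bab class by one step
        (hypomorphic alleles).
    rn_null_kappa
        Bab scale applied automatically under an rn-null perturbation
        (Bab is partially activated by Rn and weaker in rn mutants).
    grid_size
        Number of uniform radial sample positions; samples sit at cell
        centres so ring boundaries never coincide with a sample.
    ring_boundaries
        Radii separating the reference rings, centre -> periphery:
        ``(r_76, r_65, r_54, r_43, r_32, r_21)``; the boundary between
        R(4) and R(5) is the central fold.
    """

    theta_ap: float = 0.55
    theta_dac: float = 0.40
    theta_rn_low: float = 0.12
    theta_rn_high: float = 0.70
    theta_bar_center: float = 0.85
    bab_profile: dict = field(default_factory=lambda: dict(DEFAULT_BAB_PROFILE))
    kappa: float = 1.0
    kappa_cutoff: float = 0.8
    rn_null_kappa: float = 0.6
    grid_size: int = 1000
    ring_boundaries: tuple = (0.15, 0.30, 0.45, 0.60, 0.75, 0.88)

    def validate(self) -> None:
        if not (0 < self.theta_rn_low < self.theta_rn_high <= 1):
            raise ValidationError(
                "require 0 < theta_rn_low < theta_rn_high <= 1, got "
                f"{self.theta_rn_low}, {self.theta_rn_high}"
            )
        if not (self.theta_bar_center > self.theta_ap > self.theta_dac):
            raise ValidationError(
                "require theta_bar_center > theta_ap > theta_dac, got "
                f"{self.theta_bar_center}, {self.theta_ap}, {self.theta_dac}"
            )
        if not (0 < self.kappa <= 1):
            raise ValidationError(f"kappa must be in (0, 1], got {self.kappa}")
        if self.grid_size < 16:
            raise ValidationError("grid_size too small to resolve the rings")
        b = self.ring_boundaries
        if len(b) != 6 or any(b[i] >= b[i + 1] for i in range(5)) or b[0] <= 0 or b[-1] >= 1:
            raise ValidationError(f"ring_boundaries must be 6 increasing radii in (0,1), got {b}")
        missing = [lab for lab in RING_LABELS if lab not in self.bab_profile]
        if missing:
            raise ValidationError(f"bab_profile missing rings: {missing}")

    # -- plain-text key=value config -------------------------------------
    def to_config(self) -> str:
        lines = [
            f"theta_ap={self.theta_ap}",
            f"theta_dac={self.theta_dac}",
            f"theta_rn_low={self.theta_rn_low}",
            f"theta_rn_high={self.theta_rn_high}",
            f"theta_bar_center={self.theta_bar_center}",
            f"kappa={self.kappa}",
            f"kappa_cutoff={self.kappa_cutoff}",
            f"rn_null_kappa={self.rn_null_kappa}",
            f"grid_size={self.grid_size}",
            "ring_boundaries=" + ",".join(str(x) for x in self.ring_boundaries),
            "bab_profile=" + ",".join(
                f"{lab}:{self.bab_profile[lab].name}" for lab in RING_LABELS
            ),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ThresholdParams":
        kv = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"config line is not key=value: {line!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        kwargs = {}
        for name in ("theta_ap", "theta_dac", "theta_rn_low", "theta_rn_high",
                     "theta_bar_center", "kappa", "kappa_cutoff", "rn_null_kappa"):
            if name in kv:
                kwargs[name] = float(kv.pop(name))
        if "grid_size" in kv:
            kwargs["grid_size"] = int(kv.pop("grid_size"))
        if "ring_boundaries" in kv:
            kwargs["ring_boundaries"] = tuple(float(x) for x in kv.pop("ring_boundaries").split(","))
        if "bab_profile" in kv:
            prof = {}
            for item in kv.pop("bab_profile").split(","):
                lab, name = item.split(":")
                prof[lab] = BabClass[name]
            kwargs["bab_profile"] = prof
        if kv:
            raise ValidationError(f"unknown config keys: {sorted(kv)}")
        params = cls(**kwargs)
        params.validate()
        return params


def default_params() -> ThresholdParams:
    """Default parameterization reproducing the reference seven-ring sequence."""
    p = ThresholdParams()
    p.validate()
    return p


@dataclass(frozen=True)
class Perturbation:
    """A single genetic manipulation of the network.

    modes
    -----
    null
        Loss of function: the gene product is absent everywhere.
    force_on_in_domain
        GAL4/UAS overexpression: the factor is ON wherever the named driver
        domain is active (e.g. ``rn_active`` for an rn-GAL4 driver).
    scale_level
        Hypomorph: multiply the graded level (Bab) by ``magnitude`` in (0, 1].
    boost_morphogen
        Constitutively active signalling: add ``magnitude`` to the effective
        morphogen level inside the driver domain (EGFR only).
    """

    gene: str
    mode: str
    domain: str = "everywhere"
    magnitude: float = 1.0
    clone_fraction: float | None = None

    def validate(self) -> None:
        if self.gene not in GENES:
            raise ValidationError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        if self.mode == "scale_level" and not (0 < self.magnitude <= 1):
            raise ValidationError(
                f"scale_level magnitude must be in (0, 1], got {self.magnitude}"
            )
        if self.mode == "boost_morphogen":
            if self.gene != "EGFR":
                raise ValidationError("boost_morphogen applies to EGFR only")
            if self.magnitude < 0:
                raise ValidationError("boost magnitude must be >= 0")
        if self.clone_fraction is not None and not (0 <= self.clone_fraction <= 1):
            raise ValidationError(
                f"clone_fraction must be in [0, 1], got {self.clone_fraction}"
            )

    def describe(self) -> str:
        s = f"{self.gene}:{self.mode}"
        if self.mode == "force_on_in_domain":
            s += f"@{self.domain}"
        if self.mode in ("scale_level", "boost_morphogen"):
            s += f"x{self.magnitude}"
        return s


_BOOL_KEYS = {"gene", "mode", "domain", "magnitude", "clone_fraction"}


def build_perturbation(spec: str) -> Perturbation:
    """Parse a perturbation from ``"key=value key=value"`` text.

    Examples: ``"gene=rn mode=null"``,
    ``"gene=Bar mode=force_on_in_domain domain=rn_active"``.
    """
    kv = {}
    for token in spec.split():
        if "=" not in token:
            raise ValidationError(f"expected key=value, got {token!r}")
        k, v = token.split("=", 1)
        if k not in _BOOL_KEYS:
            raise ValidationError(f"unknown key {k!r} in perturbation spec")
        kv[k] = v
    if "gene" not in kv or "mode" not in kv:
        raise ValidationError("perturbation spec must name a gene and a mode")
    pert = Perturbation(
        gene=kv["gene"],
        mode=kv["mode"],
        domain=kv.get("domain", "everywhere"),
        magnitude=float(kv.get("magnitude", 1.0)),
        clone_fraction=float(kv["clone_fraction"]) if "clone_fraction" in kv else None,
    )
    pert.validate()
    return pert


@dataclass
class DiscState:
    """Per-position factor state along the radial axis.

    Arrays are indexed by position, ``positions`` ascending from the disc
    centre (r -> 0) to the periphery (r -> 1).  ``bab_class`` holds the
    authoritative ordinal Bab level; ``bab_level`` is an informational
    numeric profile (class step scaled by the effective kappa).
    ``central_fold`` is the radius of the outer boundary of the Ap-ON
    region, or None when the fold is morphologically absent (Bar
    overexpression) or Ap is OFF everywhere.
    """

    positions: np.ndarray
    morphogen: np.ndarray
    morphogen_effective: np.ndarray
    dac: np.ndarray
    ap: np.ndarray
    rn: np.ndarray
    bar: np.ndarray
    bab_class: np.ndarray
    bab_level: np.ndarray
    central_fold: float | None
    dac_reduced: np.ndarray
    perturbations: tuple = ()

    @property
    def bab(self) -> np.ndarray:
        """Bab ON mask: ON iff the level class is not absent."""
        return self.bab_class > 0

    def factor_on(self, factor: str) -> np.ndarray:
        return {"Dac": self.dac, "Rn": self.rn, "Ap": self.ap,
                "Bar": self.bar, "Bab": self.bab}[factor]

    def code_at(self, i: int) -> frozenset:
        return frozenset(f for f in FACTORS if self.factor_on(f)[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "E": self.morphogen,
            "E_effective": self.morphogen_effective,
            "dac": self.dac.astype(int),
            "ap": self.ap.astype(int),
            "rn": self.rn.astype(int),
            "bar": self.bar.astype(int),
            "bab_class": [BabClass(c).name for c in self.bab_class],
            "dac_reduced": self.dac_reduced.astype(int),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def equal_state(self, other: "DiscState") -> bool:
        same_fold = (
            (self.central_fold is None and other.central_fold is None)
            or (self.central_fold is not None and other.central_fold is not None
                and np.isclose(self.central_fold, other.central_fold))
        )
        return bool(
            same_fold
            and np.array_equal(self.dac, other.dac)
            and np.array_equal(self.ap, other.ap)
            and np.array_equal(self.rn, other.rn)
            and np.array_equal(self.bar, other.bar)
            and np.array_equal(self.bab_class, other.bab_class)
        )


def _check_perturbations(perturbations) -> tuple:
    perts = tuple(perturbations)
    for p in perts:
        if not isinstance(p, Perturbation):
            raise ValidationError(f"not a Perturbation: {p!r}")
        p.validate()
    seen: dict[str, Perturbation] = {}
    for p in perts:
        if p.gene in seen:
            raise ValidationError(
                "contradictory perturbations on gene "
                f"{p.gene!r}: {seen[p.gene].describe()} vs {p.describe()}"
            )
        seen[p.gene] = p
    return perts


def _domain_mask(domain: str, E_base: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Driver-domain predicate, evaluated on the unperturbed wild-type pattern."""
    if domain == "everywhere":
        return np.ones_like(E_base, dtype=bool)
    if domain == "rn_active":
        return (E_base > params.theta_rn_low) & (E_base <= params.theta_rn_high)
    if domain == "ap_endogenous":
        return E_base >= params.theta_ap
    if domain == "dac_active":
        return E_base < params.theta_dac
    raise ValidationError(f"unknown domain {domain!r}")


def _ring_index(positions: np.ndarray, boundaries: tuple) -> np.ndarray:
    """Reference ring label index (0 = R(1) periphery ... 6 = R(7) centre)."""
    # np.searchsorted over centre->periphery boundaries gives 0..6 from centre
    inner_count = np.searchsorted(np.asarray(boundaries), positions, side="right")
    return 6 - inner_count  # invert so 0 is the outermost ring


def simulate_disc(params: ThresholdParams, perturbations=()) -> DiscState:
    """Deterministic feed-forward evaluation of the prepatterning network.

    Rule pass, in order (E_eff is the boosted morphogen, E the baseline):

    1.  E_eff = E + boost inside the boost driver domain.
    2.  Dac ON iff E < theta_dac (baseline; see module docstring).
    3.  Ap ON iff E_eff >= theta_ap.
    4.  Rn ON iff theta_rn_low < E_eff <= theta_rn_high; forced OFF by
        rn-null, and wherever an Ap overexpression is active within the
        endogenous Ap zone (increased Ap represses Rn there).
    5.  Bar ON iff Dac OFF and E < theta_bar_center (baseline) and
        (Rn OFF or Ap ON); a Bar force_on adds its driver domain.
    6.  Bab: per-ring level class, demoted one step when the effective
        kappa falls below ``kappa_cutoff``; rn-null applies
        ``rn_null_kappa``; ON iff class is not absent.

    Side rules: Ap overexpression reduces Dac where its driver overlaps the
    Dac domain (recorded as a ``dac_reduced`` flag; the Dac call itself is
    kept, matching the observed decrease rather than loss).  Bar
    overexpression abolishes the central fold but leaves Ap, Bab and Dac
    untouched.
    """
    params.validate()
    perts = _check_perturbations(perturbations)
    by_gene = {p.gene: p for p in perts}

    n = params.grid_size
    r = (np.arange(n) + 0.5) / n
    E = 1.0 - r

    # 1. morphogen boost
    E_eff = E.copy()
    boost = by_gene.get("EGFR")
    if boost is not None and boost.mode == "boost_morphogen":
        E_eff = E_eff + boost.magnitude * _domain_mask(boost.domain, E, params)
    if np.any(~np.isfinite(E_eff)) or np.any(E_eff < 0):
        raise ValidationError("morphogen levels must be finite and >= 0")

    # 2. Dac
    dac = E < params.theta_dac
    dac_pert = by_gene.get("dac")
    if dac_pert is not None:
        if dac_pert.mode == "null":
            dac = np.zeros(n, dtype=bool)
        elif dac_pert.mode == "force_on_in_domain":
            dac = dac | _domain_mask(dac_pert.domain, E, params)

    # 3. Ap
    ap_pert = by_gene.get("ap")
    ap = E_eff >= params.theta_ap
    ap_oe_mask = np.zeros(n, dtype=bool)
    if ap_pert is not None:
        if ap_pert.mode == "null":
            ap = np.zeros(n, dtype=bool)
        elif ap_pert.mode == "force_on_in_domain":
            ap_oe_mask = _domain_mask(ap_pert.domain, E, params)
            ap = ap | ap_oe_mask

    # Ap-OE reduces Dac where the driver overlaps the Dac domain
    dac_reduced = ap_oe_mask & dac

    # 4. Rn
    rn = (E_eff > params.theta_rn_low) & (E_eff <= params.theta_rn_high)
    rn_pert = by_gene.get("rn")
    rn_is_null = rn_pert is not None and rn_pert.mode == "null"
    if rn_is_null:
        rn = np.zeros(n, dtype=bool)
    if np.any(ap_oe_mask):
        rn = rn & ~(ap_oe_mask & (E_eff >= params.theta_ap))

    # 5. Bar
    bar = (~dac) & (E < params.theta_bar_center) & (~rn | ap)
    bar_pert = by_gene.get("Bar")
    bar_forced = bar_pert is not None and bar_pert.mode == "force_on_in_domain"
    if bar_pert is not None:
        if bar_pert.mode == "null":
            bar = np.zeros(n, dtype=bool)
        elif bar_forced:
            bar = bar | _domain_mask(bar_pert.domain, E, params)

    # 6. Bab
    kappa = params.kappa
    bab_pert = by_gene.get("bab")
    if bab_pert is not None and bab_pert.mode == "scale_level":
        kappa *= bab_pert.magnitude
    if rn_is_null:
        kappa *= params.rn_null_kappa
    ring_idx = _ring_index(r, params.ring_boundaries)
    profile = [params.bab_profile[RING_LABELS[i]] for i in range(7)]
    bab_class = np.array([int(profile[i]) for i in ring_idx], dtype=int)
    if kappa < params.kappa_cutoff:
        bab_class = np.maximum(bab_class - 1, 0)
    if bab_pert is not None and bab_pert.mode == "null":
        bab_class = np.zeros(n, dtype=int)
    bab_level = kappa * bab_class / 3.0

    # central fold: outer boundary of the Ap-ON region
    if bar_forced or not np.any(ap):
        central_fold = None
    else:
        outermost = r[ap].max()
        central_fold = float(min(outermost + 0.5 / n, 1.0))

    return DiscState(
        positions=r,
        morphogen=E,
        morphogen_effective=E_eff,
        dac=dac,
        ap=ap,
        rn=rn,
        bar=bar,
        bab_class=bab_class,
        bab_level=bab_level,
        central_fold=central_fold,
        dac_reduced=dac_reduced,
        perturbations=perts,
    )
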