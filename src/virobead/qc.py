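"""Platform quantitative QC.

Loading statistics (Poisson inversion from the fluorescence-positive bead
rate), particle-concentration estimation, the dilution rule, per-bead
classification against reference genomes, genome breadth, and the
Lorenz-curve / Gini-coefficient measure of MDA amplification bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DILUTION_THRESHOLD = 0.20


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class BeadClassification:
    bead_id: str
    majority_ref: str | None
    minor_viral_fraction: float
    contaminated: bool
    background_fraction: float
    background_dominated: bool


def estimate_mean_loading(p_positive: float) -> float:
    """Mean particles per bead from the positive-bead fraction.

    Under Poisson loading, P(bead positive) = 1 - exp(-lambda), so
    lambda = -ln(1 - p).
    """
    if p_positive < 0:
        raise ParameterError("p_positive must be >= 0")
    if p_positive >= 1:
        raise ParameterError("p_positive = 1 leaves lambda undefined")
    return -math.log1p(-p_positive)


def multiple_loading_probability(lam: float) -> float:
    """P(>= 2 particles | bead positive) = 1 - lam*e^-lam / (1 - e^-lam)."""
    if lam <= 0:
        return 0.0
    return 1.0 - lam * math.exp(-lam) / (1.0 - math.exp(-lam))


def bead_volume_ml(diameter_um: float) -> float:
    """Volume of a spherical bead in mL; V = (pi/6) d^3."""
    if diameter_um <= 0:
        raise ParameterError("diameter must be > 0")
    d_cm = diameter_um * 1e-4
    return math.pi / 6.0 * d_cm**3


def concentration_from_loading(
    lam: float, bead_diameter_um: float = 30.0, dilution_factor: float = 2.0
) -> float:
    """Particles per mL of the original suspension.

    The suspension is mixed 1:1 with molten agarose before droplet
    generation, hence the default dilution factor of 2.
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    return lam / bead_volume_ml(bead_diameter_um) * dilution_factor


def dilution_decision(p_positive: float) -> dict:
    """Proceed/dilute rule: dilute iff the positive rate strictly exceeds 20%.

    Returns the decision together with the implied co-encapsulation
    probability among positive beads.
    """
    if not 0 <= p_positive <= 1:
        raise ParameterError("p_positive must be in [0,1]")
    lam = estimate_mean_loading(p_positive) if p_positive < 1 else math.inf
    return {
        "decision": "dilute" if p_positive > DILUTION_THRESHOLD else "proceed",
        "p_positive": p_positive,
        "mean_loading": lam,
        "p_multiple_given_positive": multiple_loading_probability(lam),
    }


def classify_bead(
    counts: dict[str, int],
    background_refs: set[str] | None = None,
    minor_threshold: float = 0.01,
    bead_id: str = "",
) -> BeadClassification:
    """Label a bead by its dominant reference and flag cross-contamination.

    ``counts`` maps reference_id -> mapped read count for one bead.  The
    majority call considers viral references only; a bead is contaminated
    when reads from non-majority viral references exceed ``minor_threshold``
    (strict) of all mapped reads.  Beads where the background reference
    out-reads every viral reference are flagged background-dominated rather
    than contaminated.
    """
    background_refs = background_refs or set()
    total = sum(counts.values())
    if total <= 0:
        return BeadClassification(bead_id, None, 0.0, False, 0.0, False)
    viral = {r: c for r, c in counts.items() if r not in background_refs and c > 0}
    bg = sum(c for r, c in counts.items() if r in background_refs)
    bg_frac = bg / total
    if not viral:
        return BeadClassification(bead_id, None, 0.0, False, bg_frac, bg > 0)
    majority = max(viral, key=lambda r: (viral[r], r))
    minor = (sum(viral.values()) - viral[majority]) / total
    return BeadClassification(
        bead_id=bead_id,
        majority_ref=majority,
        minor_viral_fraction=minor,
        contaminated=minor > minor_threshold,
        background_fraction=bg_frac,
        background_dominated=bg > viral[majority],
    )


def genome_breadth(depth: np.ndarray) -> float:
    """Fraction of reference positions with depth >= 1."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ParameterError("empty coverage vector")
    return float(np.count_nonzero(depth >= 1) / depth.size)


def lorenz_curve(depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lorenz curve of per-base depth: cumulative genome fraction vs
    cumulative depth fraction, positions sorted by increasing depth."""
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0 or depth.sum() <= 0:
        raise ParameterError("Lorenz curve undefined for zero total depth")
    x = np.sort(depth)
    cum = np.concatenate([[0.0], np.cumsum(x)]) / x.sum()
    frac = np.linspace(0.0, 1.0, depth.size + 1)
    return frac, cum


def gini_coefficient(depth: np.ndarray) -> float:
    """Gini coefficient of per-base amplification depth.

    G = 1 - 2 * (trapezoidal area under the Lorenz curve); 0 for perfectly
    uniform coverage, approaching 1 as coverage concentrates on few sites.
    Zero-depth positions are included, making this the stricter measure of
    MDA bias.
    """
    frac, cum = lorenz_curve(depth)
    area = float(np.trapezoid(cum, frac))
    return 1.0 - 2.0 * area
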