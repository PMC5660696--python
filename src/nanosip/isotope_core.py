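"""Isotope-ratio arithmetic and two-pool label mixing.

Conversions among the three scales used in stable-isotope probing —
rare/abundant isotope ratio ``R``, atom fraction / atom percent, and δ
notation (per mil deviation from an international standard) — plus the
concentration-weighted mass balance that gives the final atom percent of a
substrate pool after a labeled spike is added to the natural background.

Two isotope systems are predefined: ¹³C/¹²C against VPDB and ¹⁵N/¹⁴N against
atmospheric N₂.  Atom percent is the natural scale for highly enriched SIP
samples; δ notation is retained for comparability with natural-abundance
work.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "IsotopeSystem",
    "PoolSpec",
    "CARBON",
    "NITROGEN",
    "SYSTEMS",
    "ratio_to_atom_percent",
    "atom_percent_to_ratio",
    "ratio_to_delta",
    "delta_to_ratio",
    "natural_abundance_atom_percent",
    "mix_pools",
    "position_averaged_atom_percent",
    "constants_table",
]


@dataclass(frozen=True)
class IsotopeSystem:
    """A rare/abundant isotope pair and its international reference ratio."""

    element_label: str
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.reference_ratio <= 0:
            raise ValueError("reference_ratio must be positive")


#: ¹³C/¹²C, Vienna Pee Dee Belemnite.
CARBON = IsotopeSystem("13C/12C", 0.0112372)
#: ¹⁵N/¹⁴N, atmospheric N₂.
NITROGEN = IsotopeSystem("15N/14N", 0.0036765)

SYSTEMS: dict[str, IsotopeSystem] = {"C": CARBON, "N": NITROGEN}


@dataclass(frozen=True)
class PoolSpec:
    """A substrate pool: concentration (μM) and heavy-isotope atom percent."""

    concentration: float
    atom_percent: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not 0.0 <= self.atom_percent <= 100.0:
            raise ValueError("atom_percent must lie in [0, 100]")


def ratio_to_atom_percent(ratio: float) -> float:
    """Convert a rare/abundant ratio R to atom percent, 100·R/(1+R)."""
    if ratio < 0:
        raise ValueError("isotope ratio must be non-negative")
    return 100.0 * ratio / (1.0 + ratio)


def atom_percent_to_ratio(atom_percent: float) -> float:
    """Convert atom percent to a rare/abundant ratio, ap/(100−ap)."""
    if not 0.0 <= atom_percent < 100.0:
        raise ValueError("atom percent must lie in [0, 100); the ratio "
                         "diverges at 100")
    return atom_percent / (100.0 - atom_percent)


def ratio_to_delta(ratio: float, system: IsotopeSystem) -> float:
    """δ value (‰) of a ratio against the system's reference standard."""
    if ratio < 0:
        raise ValueError("isotope ratio must be non-negative")
    return (ratio / system.reference_ratio - 1.0) * 1000.0


def delta_to_ratio(delta: float, system: IsotopeSystem) -> float:
    """Ratio corresponding to a δ value (‰); defined for δ > −1000."""
    if delta <= -1000.0:
        raise ValueError("delta must exceed -1000 per mil")
    return system.reference_ratio * (1.0 + delta / 1000.0)


def natural_abundance_atom_percent(system: IsotopeSystem) -> float:
    """Atom percent of the heavy isotope at the reference standard's ratio."""
    return ratio_to_atom_percent(system.reference_ratio)


def mix_pools(label: PoolSpec, natural: PoolSpec) -> float:
    """Final atom percent of a substrate pool after spiking with label.

    Concentration-weighted average of the two pools' atom percents,
    ``(c_l·ap_l + c_n·ap_n) / (c_l + c_n)``.  Mixing is at the level of
    substrate molecules: a singly-labeled substrate sold at 99 atom %
    isotopic purity is treated as a 99 atom % pool, which is the convention
    that reproduces published final ratios for single-position labels.  For
    per-carbon-position bookkeeping see
    :func:`position_averaged_atom_percent`.
    """
    total = label.concentration + natural.concentration
    if total <= 0:
        raise ValueError("at least one pool must have positive concentration")
    return (
        label.concentration * label.atom_percent
        + natural.concentration * natural.atom_percent
    ) / total


def position_averaged_atom_percent(
    purity_atom_percent: float,
    n_labeled_positions: int,
    n_positions: int,
    natural_atom_percent: float | None = None,
) -> float:
    """Atom percent over *all* carbon positions of a position-labeled substrate.

    A [1-¹³C] substrate carries the label at one of ``n_positions`` carbons;
    the remaining positions sit at natural abundance.  This diverges from the
    molecule-level convention of :func:`mix_pools` and from published final
    ratios computed under it; it is provided for users who need true
    whole-molecule atom fractions.
    """
    if not 0 < n_labeled_positions <= n_positions:
        raise ValueError("need 0 < n_labeled_positions <= n_positions")
    if natural_atom_percent is None:
        natural_atom_percent = natural_abundance_atom_percent(CARBON)
    n_nat = n_positions - n_labeled_positions
    return (
        n_labeled_positions * purity_atom_percent
        + n_nat * natural_atom_percent
    ) / n_positions


def constants_table() -> str:
    """JSON dump of the predefined isotope standards, for run provenance."""
    rows = {
        key: {
            "element_label": sys.element_label,
            "reference_ratio": sys.reference_ratio,
            "natural_abundance_atom_percent": natural_abundance_atom_percent(sys),
        }
        for key, sys in SYSTEMS.items()
    }
    return json.dumps(rows, indent=2)


def _self_check() -> None:
    # natural abundances implied by the standards, to 4 decimals
    assert math.isclose(natural_abundance_atom_percent(CARBON), 1.1112, abs_tol=5e-5)
    assert math.isclose(natural_abundance_atom_percent(NITROGEN), 0.3663, abs_tol=5e-5)


_self_check()
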