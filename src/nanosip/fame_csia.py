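"""Compound-specific isotope analysis of fatty acid methyl esters.

Fatty acids are measured by GC-IRMS as their methyl esters (FAMEs), so the
measured δ¹³C includes one carbon contributed by the methanol derivatization
reagent.  The free-fatty-acid composition is recovered by the standard
methyl-carbon correction

    δ13C_FA = (δ13C_FAME − (1 − f)·δ13C_MeOH) / f

where f = X/(X+1) is the fractional carbon contribution of an X-carbon fatty
acid to its ester.  This module also parses the CX:Yn-Z fatty-acid
nomenclature (with iso/anteiso, cyclopropane, hydroxy and dimethyl variants)
and summarizes per-fatty-acid treatment enrichment relative to a control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotope_core import CARBON, atom_percent_to_ratio, delta_to_ratio, ratio_to_atom_percent, ratio_to_delta
from . import stats_tests

__all__ = [
    "DEFAULT_DELTA_MEOH",
    "FattyAcidDescriptor",
    "FameRecord",
    "parse_fa_name",
    "fa_fraction",
    "correct_fame_delta",
    "esterify_delta",
    "correct_fame_delta_exact",
    "correct_records",
    "enrichment_table",
    "read_fame_csv",
    "write_fame_csv",
]

#: δ¹³C of BF₃-methanol derivatization reagent (‰ vs VPDB), the default
#: used when a record does not carry its own methanol value.
DEFAULT_DELTA_MEOH = -37.9

MODIFIERS = ("none", "iso", "anteiso", "cyclopropane", "hydroxy", "dimethyl")


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Parsed CX:Yn-Z fatty-acid name.

    ``n_carbons`` is the carbon chain length X, ``n_double_bonds`` the number
    of double bonds Y, ``omega_position`` the position Z of the first double
    bond counted from the methyl end (absent for saturated acids), and
    ``modifier`` one of iso / anteiso / cyclopropane / hydroxy / dimethyl /
    none.
    """

    n_carbons: int
    n_double_bonds: int
    omega_position: int | None
    modifier: str
    raw_name: str

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError("fatty acids have at least 2 carbons")
        if self.n_double_bonds < 0:
            raise ValueError("number of double bonds cannot be negative")
        if self.omega_position is not None and self.n_double_bonds < 1:
            raise ValueError("omega position given for a saturated acid")
        if self.modifier not in MODIFIERS:
            raise ValueError(f"unknown modifier {self.modifier!r}")

    def canonical_name(self) -> str:
        name = f"C{self.n_carbons}:{self.n_double_bonds}"
        if self.omega_position is not None:
            name += f"n-{self.omega_position}"
        if self.modifier == "iso":
            name += " iso"
        elif self.modifier == "anteiso":
            name += " anteiso"
        elif self.modifier == "hydroxy":
            name += "-OH"
        elif self.modifier == "cyclopropane":
            name = "cy" + name
        elif self.modifier == "dimethyl":
            name = "diMe " + name.split(":")[0]
        return name


@dataclass
class FameRecord:
    """One GC-IRMS measurement of a fatty acid methyl ester."""

    fa: FattyAcidDescriptor
    delta_fame: float
    treatment: str
    replicate: int
    delta_meoh: float = DEFAULT_DELTA_MEOH
    f: float = field(init=False)
    delta_fa: float | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        self.f = fa_fraction(self.fa.n_carbons)


# --- nomenclature -----------------------------------------------------------

_CORE = re.compile(
    r"""^
    (?P<cy>cy)?\s*C\s*(?P<x>\d+)\s*:\s*(?P<y>\d+)      # CX:Y
    (?:\s*n\s*-?\s*(?P<z>\d+))?                        # optional n-Z
    (?P<oh>\s*-\s*OH)?                                 # optional hydroxy
    (?:\s+(?P<branch>iso|anteiso))?                    # optional branching
    $""",
    re.IGNORECASE | re.VERBOSE,
)
# "9-10diMe C16" dialect used for cyclopropane/dimethyl FAMEs
_DIME = re.compile(
    r"^(?:(?P<pos>\d+\s*-\s*\d+)\s*)?diMe\s+C\s*(?P<x>\d+)(?:\s*:\s*(?P<y>\d+))?$",
    re.IGNORECASE,
)
_BRANCH_PREFIX = re.compile(r"^(?P<branch>iso|anteiso)\s+(?P<rest>.+)$", re.IGNORECASE)


class FattyAcidNameError(ValueError):
    """Raised when a fatty-acid name cannot be parsed."""


def parse_fa_name(name: str) -> FattyAcidDescriptor:
    """Parse a fatty-acid name in any of the common CX:Y dialects.

    Accepted forms include ``C16:0``, ``C18:1n-7``, ``C16:0-OH``,
    ``C17:0 anteiso`` / ``anteiso C17:0``, ``cyC17:0`` and ``9-10diMe C16``.
    Whitespace and case are not significant.  Unknown suffixes raise
    :class:`FattyAcidNameError` naming the offending token rather than being
    guessed at.
    """
    raw = name
    name = name.strip()
    if not name:
        raise FattyAcidNameError("empty fatty-acid name")

    m = _DIME.match(name)
    if m:
        return FattyAcidDescriptor(
            n_carbons=int(m.group("x")),
            n_double_bonds=int(m.group("y") or 0),
            omega_position=None,
            modifier="dimethyl",
            raw_name=raw,
        )

    branch = None
    m = _BRANCH_PREFIX.match(name)
    if m:
        branch = m.group("branch").lower()
        name = m.group("rest")

    m = _CORE.match(name)
    if not m:
        token = name.split()[-1] if name.split() else name
        raise FattyAcidNameError(
            f"cannot parse fatty-acid name {raw!r} (offending token {token!r})"
        )
    if branch and m.group("branch"):
        raise FattyAcidNameError(f"duplicate branching modifier in {raw!r}")
    branch = branch or (m.group("branch") or "").lower() or None

    modifier = "none"
    if m.group("cy"):
        modifier = "cyclopropane"
    if m.group("oh"):
        if modifier != "none":
            raise FattyAcidNameError(f"conflicting modifiers in {raw!r}")
        modifier = "hydroxy"
    if branch:
        if modifier != "none":
            raise FattyAcidNameError(f"conflicting modifiers in {raw!r}")
        modifier = branch

    z = m.group("z")
    return FattyAcidDescriptor(
        n_carbons=int(m.group("x")),
        n_double_bonds=int(m.group("y")),
        omega_position=int(z) if z is not None else None,
        modifier=modifier,
        raw_name=raw,
    )


# --- methyl-carbon correction ----------------------------------------------

def fa_fraction(n_carbons: int) -> float:
    """Fractional carbon contribution of an X-carbon free fatty acid to its
    methyl ester: X/(X+1)."""
    if n_carbons < 1:
        raise ValueError("carbon count must be at least 1")
    return n_carbons / (n_carbons + 1)


def correct_fame_delta(delta_fame: float, f: float, delta_meoh: float = DEFAULT_DELTA_MEOH) -> float:
    """Recover free-fatty-acid δ¹³C from the measured FAME δ¹³C.

    Linear δ-scale mixing: δ_FA = (δ_FAME − (1−f)·δ_MeOH)/f.  This matches
    the convention of the published CSIA workflow; it is a first-order
    approximation of atom-fraction mixing that is excellent at natural
    abundance and percent-level enrichment.  For strongly ¹³C-enriched SIP
    samples (δ of thousands of ‰) use :func:`correct_fame_delta_exact`.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie strictly between 0 and 1")
    return (delta_fame - (1.0 - f) * delta_meoh) / f


def esterify_delta(delta_fa: float, f: float, delta_meoh: float = DEFAULT_DELTA_MEOH) -> float:
    """Forward esterification mixing, the exact inverse of
    :func:`correct_fame_delta`: δ_FAME = f·δ_FA + (1−f)·δ_MeOH."""
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie strictly between 0 and 1")
    return f * delta_fa + (1.0 - f) * delta_meoh


def correct_fame_delta_exact(delta_fame: float, f: float, delta_meoh: float = DEFAULT_DELTA_MEOH) -> float:
    """Methyl-carbon correction carried out on the atom-fraction scale.

    Converts all δ values to ¹³C atom fractions, applies the carbon-weighted
    mixing x_FAME = f·x_FA + (1−f)·x_MeOH exactly, and converts back.
    Coincides with :func:`correct_fame_delta` to first order near natural
    abundance; deviates for heavily labeled material.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie strictly between 0 and 1")
    x_fame = ratio_to_atom_percent(delta_to_ratio(delta_fame, CARBON))
    x_meoh = ratio_to_atom_percent(delta_to_ratio(delta_meoh, CARBON))
    x_fa = (x_fame - (1.0 - f) * x_meoh) / f
    if not 0.0 <= x_fa < 100.0:
        raise ValueError("corrected atom fraction outside [0, 100)")
    return ratio_to_delta(atom_percent_to_ratio(x_fa), CARBON)


def correct_records(records: Iterable[FameRecord], exact: bool = False) -> list[FameRecord]:
    """Apply the methyl-carbon correction in place to a batch of records."""
    out = []
    for rec in records:
        corr = correct_fame_delta_exact if exact else correct_fame_delta
        rec.delta_fa = corr(rec.delta_fame, rec.f, rec.delta_meoh)
        out.append(rec)
    return out


# --- summarization ----------------------------------------------------------

def _records_frame(records: Sequence[FameRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.fa.canonical_name() for r in records],
            "treatment": [r.treatment for r in records],
            "replicate": [r.replicate for r in records],
            "delta_fame": [r.delta_fame for r in records],
            "delta_meoh": [r.delta_meoh for r in records],
            "delta_fa": [r.delta_fa for r in records],
        }
    )


def enrichment_table(
    records: Sequence[FameRecord],
    control_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-fatty-acid, per-treatment enrichment summary.

    Returns one row per (fatty acid, treatment) with the mean and sd of the
    corrected δ¹³C_FA, the difference of the mean from the control mean, and
    — where every treatment of that fatty acid has at least two replicates —
    the Van der Waerden k-sample p-value across treatments and a compact
    letter display (treatments sharing a letter are not significantly
    different in Holm-adjusted pairwise tests).  Rows from fatty acids with a
    single replicate anywhere are flagged ``insufficient_replicates`` and
    carry no test.
    """
    if not records:
        raise ValueError("no records given")
    if any(r.delta_fa is None for r in records):
        records = correct_records(list(records))
    df = _records_frame(records)
    if control_label not in set(df["treatment"]):
        raise ValueError(f"control treatment {control_label!r} not present")

    rows = []
    for fa_name, sub in df.groupby("name", sort=True):
        counts = sub.groupby("treatment")["delta_fa"].count()
        testable = (counts >= 2).all() and len(counts) >= 2
        control_mean = sub.loc[sub["treatment"] == control_label, "delta_fa"].mean()

        p_value = np.nan
        letters: dict[str, str] = {}
        if testable:
            grouped = stats_tests.GroupedSamples(
                values=sub["delta_fa"].to_numpy(),
                group=sub["treatment"].to_numpy(),
            )
            if np.ptp(sub["delta_fa"].to_numpy()) == 0:
                p_value = 1.0
                letters = {t: "a" for t in counts.index}
            else:
                p_value = stats_tests.van_der_waerden(grouped).p_value
                letters = stats_tests.pairwise_letters(grouped, alpha=alpha).letters

        for treatment, cell in sub.groupby("treatment"):
            mean = cell["delta_fa"].mean()
            rows.append(
                {
                    "name": fa_name,
                    "treatment": treatment,
                    "n": len(cell),
                    "mean_delta_fa": mean,
                    "sd_delta_fa": cell["delta_fa"].std(ddof=1) if len(cell) > 1 else np.nan,
                    "diff_from_control": mean - control_mean,
                    "vdw_p": p_value,
                    "letters": letters.get(treatment, ""),
                    "significant_vs_control": bool(
                        testable
                        and treatment != control_label
                        and letters
                        and not (set(letters.get(treatment, "")) & set(letters.get(control_label, "")))
                    ),
                    "flag": "" if testable else "insufficient_replicates",
                }
            )
    return pd.DataFrame(rows)


# --- CSV I/O ----------------------------------------------------------------

def read_fame_csv(path: str | Path, delta_meoh: float = DEFAULT_DELTA_MEOH) -> list[FameRecord]:
    """Read FAME measurements from CSV.

    Expected columns: ``name``, ``treatment``, ``replicate``, ``delta_fame``;
    optional ``delta_meoh`` overrides the module default per row.
    """
    df = pd.read_csv(path)
    required = {"name", "treatment", "replicate", "delta_fame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rec = FameRecord(
            fa=parse_fa_name(str(row["name"])),
            delta_fame=float(row["delta_fame"]),
            treatment=str(row["treatment"]),
            replicate=int(row["replicate"]),
            delta_meoh=float(row["delta_meoh"]) if "delta_meoh" in df.columns else delta_meoh,
        )
        records.append(rec)
    return records


def write_fame_csv(records: Sequence[FameRecord], path: str | Path) -> None:
    """Write records (including corrected δ_FA when present) to CSV."""
    _records_frame(records).to_csv(path, index=False)
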