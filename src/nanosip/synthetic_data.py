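"""Ground-truthed synthetic inputs for the single-cell SIP pipeline.

Two forward models:

* a NanoSIMS ion-image simulator that plants coccoid cells of known diameter
  and known per-cell enrichment fraction r on a raster, converts r to
  isotopologue atom fractions through the label-mixing model, and draws
  independent Poisson counts per pixel, plane and channel — the physics of
  ion counting.  Sulfur globules appear as zero-emission holes inside cells.
  Every simulated field ships with a truth table (center, diameter, r, atom
  fractions) so that segmentation and quantification can be scored exactly.

* a CSIA-FAME table generator that plants per-fatty-acid, per-treatment
  δ¹³C effects plus replicate noise and emits *ester* δ values through the
  forward methyl-carbon mixing, so the analysis must invert the
  derivatization correction to recover the planted truth.

A preset reproduces the seven-treatment incubation design of the mat study
this package models: control, acetate / pyruvate / bicarbonate each in light
and dark (all with ¹⁵N-ammonium co-labeling), in triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fame_csia import DEFAULT_DELTA_MEOH, FameRecord, esterify_delta, parse_fa_name
from .flux_model import IncubationConfig
from .isotope_core import (
    CARBON,
    NITROGEN,
    PoolSpec,
    mix_pools,
    natural_abundance_atom_percent,
)
from .nanosims_roi import CHANNELS, IonCountStack

__all__ = [
    "EnrichmentDistribution",
    "MatScenario",
    "FameScenario",
    "simulate_stack",
    "simulate_fame_table",
    "paper_preset",
    "TREATMENTS",
]

TREATMENTS = ("control", "AceL", "AceD", "PyrL", "PyrD", "CO3L", "CO3D")


@dataclass(frozen=True)
class EnrichmentDistribution:
    """Distribution of per-cell enrichment fractions r in [0, 1].

    ``kind`` is one of:

    * ``constant`` — every cell at ``mean``;
    * ``normal`` — Gaussian(mean, sd), clipped to [0, 1];
    * ``bimodal`` — a zero-inflated mixture: a fraction ``active_fraction``
      of cells draw Gaussian(mean, sd) clipped to [0, 1], the rest are
      inactive at r = 0.  Models the active/inactive subpopulation
      heterogeneity seen in natural mats.
    """

    kind: str = "constant"
    mean: float = 0.0
    sd: float = 0.0
    active_fraction: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, float(self.mean))
        if self.kind == "normal":
            return np.clip(rng.normal(self.mean, self.sd, size=n), 0.0, 1.0)
        if self.kind == "bimodal":
            active = rng.random(n) < self.active_fraction
            r = np.zeros(n)
            r[active] = np.clip(
                rng.normal(self.mean, self.sd, size=int(active.sum())), 0.0, 1.0
            )
            return r
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class MatScenario:
    """Complete recipe for one simulated NanoSIMS field of a coccoid mat.

    Ion yields are expected counts per pixel per plane inside a cell at
    full emission; the background emits ``background_fraction`` of the
    in-cell yield at natural isotopic abundance.  Sulfur globules are
    zero-yield discs punched into cells across all channels.
    """

    n_cells: int = 30
    field_size_um: float = 25.0
    raster: int = 256
    n_planes: int = 28
    dwell_ms: float = 1.0
    diameter_mean_um: float = 1.67
    diameter_sd_um: float = 0.12
    r_carbon: EnrichmentDistribution = EnrichmentDistribution()
    r_nitrogen: EnrichmentDistribution = EnrichmentDistribution()
    carbon_incubation: IncubationConfig | None = None
    nitrogen_incubation: IncubationConfig | None = None
    yield_C: float = 30.0
    yield_CN: float = 60.0
    yield_S: float = 15.0
    background_fraction: float = 0.05
    globule_mean_per_cell: float = 0.0
    globule_radius_um: float = 0.25
    allow_touching: bool = False
    treatment: str = "control"
    replicate: int = 1
    seed: int = 0

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um / self.raster


def _atom_fraction(r: np.ndarray, incubation: IncubationConfig | None,
                   natural_ap: float) -> np.ndarray:
    """Per-cell heavy-isotope atom fraction implied by enrichment fraction r.

    Inverts the enrichment-fraction definition on the atom-percent scale:
    R_cell = R_ini + r·(R_final − R_ini).
    """
    if incubation is None:
        return np.full_like(np.asarray(r, dtype=float), natural_ap / 100.0)
    ap = incubation.R_ini + np.asarray(r, dtype=float) * (
        incubation.R_final - incubation.R_ini
    )
    return ap / 100.0


def _place_cells(scenario: MatScenario, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping cell centers (pixels) and diameters (μm)."""
    px = scenario.pixel_size_um
    diameters = np.clip(
        rng.normal(scenario.diameter_mean_um, scenario.diameter_sd_um,
                   size=scenario.n_cells),
        0.3 * scenario.diameter_mean_um, None,
    )
    radii_px = diameters / 2.0 / px
    centers: list[tuple[float, float]] = []
    order = np.argsort(-radii_px)  # place large cells first
    placed_r: list[float] = []
    max_tries = 20000
    for idx in order:
        r_px = radii_px[idx]
        lo, hi = r_px + 1, scenario.raster - r_px - 1
        if lo >= hi:
            raise ValueError("cell larger than the field")
        for attempt in range(max_tries):
            cy, cx = rng.uniform(lo, hi, size=2)
            if scenario.allow_touching or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r_px + orr + 1) ** 2
                for (oy, ox), orr in zip(centers, placed_r)
            ):
                centers.append((cy, cx))
                placed_r.append(r_px)
                break
        else:
            raise ValueError(
                f"cannot place {scenario.n_cells} non-overlapping cells in a "
                f"{scenario.raster}px field; reduce n_cells or allow touching"
            )
    # restore original cell order
    centers_arr = np.empty((scenario.n_cells, 2))
    for pos, idx in enumerate(order):
        centers_arr[idx] = centers[pos]
    return centers_arr, diameters


def simulate_stack(
    scenario: MatScenario,
    rng: np.random.Generator | None = None,
) -> tuple[IonCountStack, pd.DataFrame]:
    """Simulate one field; returns the stack and its ground-truth table.

    Pixels are assigned to a cell by pixel-center containment in the cell's
    disc, giving exact-area ground truth.  Counts are drawn independently
    Poisson per (channel, plane, pixel) with expectations
    yield·x and yield·(1−x) for the rare/abundant isotopologue channels.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.raster
    nat_C = natural_abundance_atom_percent(CARBON)
    nat_N = natural_abundance_atom_percent(NITROGEN)

    centers, diameters = _place_cells(scenario, rng)
    r_c = scenario.r_carbon.sample(scenario.n_cells, rng)
    r_n = scenario.r_nitrogen.sample(scenario.n_cells, rng)
    x_c = _atom_fraction(r_c, scenario.carbon_incubation, nat_C)
    x_n = _atom_fraction(r_n, scenario.nitrogen_incubation, nat_N)

    yy, xx = np.mgrid[0:n, 0:n]
    yy = yy + 0.5
    xx = xx + 0.5

    # emission maps: start from background
    bg = scenario.background_fraction
    yield_map = np.full((n, n), bg)
    xc_map = np.full((n, n), nat_C / 100.0)
    xn_map = np.full((n, n), nat_N / 100.0)
    s_map = np.zeros((n, n))
    cell_id_map = np.zeros((n, n), dtype=np.int32)

    px = scenario.pixel_size_um
    areas = np.zeros(scenario.n_cells, dtype=int)
    for i in range(scenario.n_cells):
        cy, cx = centers[i]
        r_px = diameters[i] / 2.0 / px
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        areas[i] = int(inside.sum())
        yield_map[inside] = 1.0
        xc_map[inside] = x_c[i]
        xn_map[inside] = x_n[i]
        s_map[inside] = 1.0
        cell_id_map[inside] = i + 1
        # sulfur globules: zero-yield holes
        n_glob = rng.poisson(scenario.globule_mean_per_cell)
        g_r_px = scenario.globule_radius_um / px
        for _ in range(n_glob):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(r_px - g_r_px, 0))
            gy, gx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            hole = (yy - gy) ** 2 + (xx - gx) ** 2 <= g_r_px**2
            yield_map[hole & inside] = 0.0
            s_map[hole & inside] = 0.0

    lam = {
        "12C": scenario.yield_C * yield_map * (1.0 - xc_map),
        "13C": scenario.yield_C * yield_map * xc_map,
        "12C14N": scenario.yield_CN * yield_map * (1.0 - xn_map),
        "12C15N": scenario.yield_CN * yield_map * xn_map,
        "32S": scenario.yield_S * s_map,
    }
    counts = np.empty((len(CHANNELS), scenario.n_planes, n, n), dtype=np.int64)
    for ci, ch in enumerate(CHANNELS):
        counts[ci] = rng.poisson(lam[ch], size=(scenario.n_planes, n, n))

    stack = IonCountStack(
        counts=counts,
        channels=CHANNELS,
        field_size_um=scenario.field_size_um,
        dwell_ms=scenario.dwell_ms,
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, scenario.n_cells + 1),
            "center_row": centers[:, 0],
            "center_col": centers[:, 1],
            "diameter_um": diameters,
            "area_px": areas,
            "r_C": r_c,
            "r_N": r_n,
            "atom_fraction_C": x_c,
            "atom_fraction_N": x_n,
            "treatment": scenario.treatment,
            "replicate": scenario.replicate,
        }
    )
    return stack, truth


@dataclass(frozen=True)
class FameScenario:
    """Recipe for a synthetic CSIA-FAME table with planted treatment effects.

    ``baseline`` maps fatty-acid name to its natural δ¹³C_FA; ``effects``
    maps treatment → fatty-acid → per-mil shift.  Replicate noise is
    Gaussian.  Records are emitted as FAME δ values through the forward
    esterification mixing.
    """

    fa_panel: tuple[str, ...] = (
        "C18:1n-7", "C16:1n-7", "C16:0", "C14:0",
        "C15:0 iso", "C17:0 anteiso", "cyC17:0", "9-10diMe C16",
    )
    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "C18:1n-7": -24.0, "C16:1n-7": -25.0, "C16:0": -26.0,
            "C14:0": -27.0, "C15:0 iso": -26.5, "C17:0 anteiso": -25.5,
            "cyC17:0": -24.5, "9-10diMe C16": -25.0,
        }
    )
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    treatments: tuple[str, ...] = ("control", "AceL", "PyrL", "CO3L")
    n_replicates: int = 3
    noise_sd: float = 2.0
    delta_meoh: float = DEFAULT_DELTA_MEOH
    seed: int = 0


def simulate_fame_table(
    scenario: FameScenario,
    rng: np.random.Generator | None = None,
) -> tuple[list[FameRecord], pd.DataFrame]:
    """Generate FAME records and the planted-truth table."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    records: list[FameRecord] = []
    truth_rows = []
    for treatment in scenario.treatments:
        shifts = scenario.effects.get(treatment, {})
        for name in scenario.fa_panel:
            base = scenario.baseline[name]
            effect = shifts.get(name, 0.0)
            for rep in range(1, scenario.n_replicates + 1):
                true_fa = base + effect + rng.normal(0.0, scenario.noise_sd)
                fa = parse_fa_name(name)
                f = fa.n_carbons / (fa.n_carbons + 1)
                rec = FameRecord(
                    fa=fa,
                    delta_fame=esterify_delta(true_fa, f, scenario.delta_meoh),
                    treatment=treatment,
                    replicate=rep,
                    delta_meoh=scenario.delta_meoh,
                )
                records.append(rec)
                truth_rows.append(
                    {
                        "name": name, "treatment": treatment, "replicate": rep,
                        "true_delta_fa": true_fa, "baseline": base,
                        "effect": effect,
                    }
                )
    return records, pd.DataFrame(truth_rows)


# --- the seven-treatment incubation preset ----------------------------------

_LABEL_PURITY_13C = 99.0
_LABEL_PURITY_15N = 98.0
_LABEL_CONC_13C = 500.0     # μM of each labeled C substrate
_LABEL_CONC_15N = 100.0     # μM labeled ammonium
_NATURAL_CONC = {"acetate": 1000.0, "pyruvate": 70.0, "bicarbonate": 1300.0,
                 "ammonium": 30.8}  # μM


def incubation_for(substrate: str, light: bool, t_hours: float = 5.0
                   ) -> IncubationConfig:
    """Incubation configuration for one substrate under the preset design,
    with R_final from the two-pool mass balance of the added label against
    the natural background pool."""
    if substrate == "ammonium":
        label = PoolSpec(_LABEL_CONC_15N, _LABEL_PURITY_15N)
        natural = PoolSpec(_NATURAL_CONC[substrate],
                           natural_abundance_atom_percent(NITROGEN))
        element = "N"
        r_ini = natural_abundance_atom_percent(NITROGEN)
    else:
        label = PoolSpec(_LABEL_CONC_13C, _LABEL_PURITY_13C)
        natural = PoolSpec(_NATURAL_CONC[substrate],
                           natural_abundance_atom_percent(CARBON))
        element = "C"
        r_ini = natural_abundance_atom_percent(CARBON)
    total_uM = label.concentration + natural.concentration
    return IncubationConfig(
        substrate=substrate,
        element=element,
        C_i=total_uM * 1e-6,
        t=t_hours,
        light=light,
        R_final=mix_pools(label, natural),
        R_ini=r_ini,
    )


_SUBSTRATE_OF = {"Ace": "acetate", "Pyr": "pyruvate", "CO3": "bicarbonate"}


def paper_preset(seed: int = 0, n_cells: int = 30) -> tuple[list[MatScenario], FameScenario]:
    """The seven-treatment × triplicate incubation design.

    Control cells sit at natural abundance (r ≡ 0); labeled treatments carry
    a bimodal active/inactive enrichment-fraction distribution, stronger in
    the light, with ¹⁵N-ammonium co-labeling everywhere except the control.
    Seeds are fanned out deterministically from ``seed``.
    """
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(TREATMENTS) * 3 + 1)
    ammonium = incubation_for("ammonium", light=True)

    scenarios: list[MatScenario] = []
    i = 0
    for treatment in TREATMENTS:
        if treatment == "control":
            carbon_inc = None
            nitrogen_inc = None
            r_c = EnrichmentDistribution("constant", 0.0)
            r_n = EnrichmentDistribution("constant", 0.0)
        else:
            light = treatment.endswith("L")
            substrate = _SUBSTRATE_OF[treatment[:-1]]
            carbon_inc = incubation_for(substrate, light)
            nitrogen_inc = ammonium
            mean_r = 0.06 if light else 0.015
            r_c = EnrichmentDistribution("bimodal", mean=mean_r, sd=mean_r / 3,
                                         active_fraction=0.7)
            r_n = EnrichmentDistribution("bimodal", mean=mean_r / 2, sd=mean_r / 6,
                                         active_fraction=0.7)
        for replicate in (1, 2, 3):
            scenarios.append(
                MatScenario(
                    n_cells=n_cells,
                    r_carbon=r_c,
                    r_nitrogen=r_n,
                    carbon_incubation=carbon_inc,
                    nitrogen_incubation=nitrogen_inc,
                    globule_mean_per_cell=1.0,
                    treatment=treatment,
                    replicate=replicate,
                    seed=int(sub_seeds[i] % (2**31)),
                )
            )
            i += 1

    effects = {
        "AceL": {"C18:1n-7": 600.0, "C16:1n-7": 150.0, "C16:0": 150.0},
        "PyrL": {"C18:1n-7": 80.0, "C16:1n-7": 40.0, "C16:0": 40.0},
        "CO3L": {"C18:1n-7": 200.0, "C16:1n-7": 250.0, "C16:0": 250.0},
    }
    fame = FameScenario(effects=effects,
                        seed=int(sub_seeds[-1] % (2**31)))
    return scenarios, fame
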