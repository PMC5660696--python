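"""End-to-end orchestration of the two analysis chains.

The NanoSIMS chain runs simulate → segment → quantify → flux → stats →
community on the seven-treatment incubation preset (or user-supplied
stacks); the CSIA chain runs fame (simulate or load a table, apply the
methyl-carbon correction, summarize treatment enrichment).  Each stage reads
the previous stage's artifacts from the output directory and writes its own,
so partial runs resume from existing intermediates.  All randomness flows
from the single config seed, fanned out per stage; every run drops a
resolved copy of its configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fame_csia, flux_model, nanosims_roi, stats_tests, synthetic_data
from .flux_model import CommunityParams
from .isotope_core import atom_percent_to_ratio
from .nanosims_roi import SegmentationParams

logger = logging.getLogger("nanosip")

STAGES = ("simulate", "segment", "quantify", "flux", "stats", "community", "fame")


class PipelineError(RuntimeError):
    """A stage failed or its upstream artifact is missing."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: Path
    seed: int = 0
    n_cells: int = 30
    raster: int = 256
    n_planes: int = 28
    yield_C: float = 30.0
    yield_CN: float = 60.0
    treatments: tuple[str, ...] = synthetic_data.TREATMENTS
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    community: CommunityParams = field(default_factory=CommunityParams)
    alpha: float = 0.05
    cell_diameter_um: float = 1.67
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None,
                  seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        com = CommunityParams(**raw.pop("community", {}))
        if "treatments" in raw:
            raw["treatments"] = tuple(raw["treatments"])
        cfg = cls(out_dir=Path(raw.pop("out_dir", out_dir or ".")),
                  segmentation=seg, community=com, **raw)
        if out_dir is not None:
            cfg.out_dir = Path(out_dir)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _write_resolved_config(config: RunConfig) -> None:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    (config.out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False)
    )


def _scenarios(config: RunConfig) -> list[synthetic_data.MatScenario]:
    scenarios, _ = synthetic_data.paper_preset(seed=config.seed,
                                               n_cells=config.n_cells)
    scenarios = [
        replace(s, raster=config.raster, n_planes=config.n_planes,
                yield_C=config.yield_C, yield_CN=config.yield_CN)
        for s in scenarios
        if s.treatment in config.treatments
    ]
    return scenarios


def _field_tag(s: synthetic_data.MatScenario) -> str:
    return f"{s.treatment}_rep{s.replicate}"


# --- stages -----------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    for s in _scenarios(config):
        tag = _field_tag(s)
        stack_path = config.out_dir / f"stack_{tag}.tiff"
        if stack_path.exists():
            logger.info("simulate: %s exists, skipping", stack_path.name)
            continue
        stack, truth = synthetic_data.simulate_stack(s)
        nanosims_roi.save_stack(stack, stack_path)
        truth.to_csv(config.out_dir / f"truth_{tag}.csv", index=False)
        logger.info("simulate: wrote %s (%d cells)", stack_path.name, s.n_cells)


def stage_segment(config: RunConfig) -> None:
    for s in _scenarios(config):
        tag = _field_tag(s)
        stack_path = config.out_dir / f"stack_{tag}.tiff"
        mask_path = config.out_dir / f"mask_{tag}.tiff"
        if not stack_path.exists():
            raise PipelineError(
                f"missing stack {stack_path}; run the 'simulate' stage first"
            )
        if mask_path.exists():
            continue
        stack = nanosims_roi.load_stack(stack_path)
        cn = nanosims_roi.accumulate_planes(stack)["12C14N"]
        mask = nanosims_roi.segment_cells(cn, stack.pixel_size_um,
                                          config.segmentation)
        nanosims_roi.save_mask(mask, mask_path)
        logger.info("segment: %s -> %d ROIs", tag, mask.n_rois)


def stage_quantify(config: RunConfig) -> None:
    for s in _scenarios(config):
        tag = _field_tag(s)
        meas_path = config.out_dir / f"measurements_{tag}.csv"
        if meas_path.exists():
            continue
        stack_path = config.out_dir / f"stack_{tag}.tiff"
        mask_path = config.out_dir / f"mask_{tag}.tiff"
        for p, producer in ((stack_path, "simulate"), (mask_path, "segment")):
            if not p.exists():
                raise PipelineError(
                    f"missing artifact {p}; run the '{producer}' stage first"
                )
        stack = nanosims_roi.load_stack(stack_path)
        mask = nanosims_roi.load_mask(mask_path)
        meas = nanosims_roi.measure_rois(stack, mask)
        df = nanosims_roi.measurements_to_frame(meas)
        df.insert(0, "treatment", s.treatment)
        df.insert(1, "replicate", s.replicate)
        df.to_csv(meas_path, index=False)


def _load_measurements(config: RunConfig) -> pd.DataFrame:
    frames = []
    for s in _scenarios(config):
        p = config.out_dir / f"measurements_{_field_tag(s)}.csv"
        if not p.exists():
            raise PipelineError(
                f"missing measurements {p}; run the 'quantify' stage first"
            )
        frames.append(pd.read_csv(p))
    df = pd.concat(frames, ignore_index=True)
    return df[df["valid"]]


def stage_flux(config: RunConfig) -> None:
    out_path = config.out_dir / "fluxes.csv"
    if out_path.exists():
        return
    df = _load_measurements(config)
    control = df[df["treatment"] == "control"]
    if control.empty:
        raise PipelineError("no control measurements; cannot set the baseline")
    r_ini = {
        "C": control["atom_percent_C"].mean(),
        "N": control["atom_percent_N"].mean(),
    }
    v_bac = flux_model.sphere_volume_litres(config.cell_diameter_um)

    rows = []
    for s in _scenarios(config):
        if s.treatment == "control":
            continue
        sub = df[(df["treatment"] == s.treatment)
                 & (df["replicate"] == s.replicate)]
        for inc, col in ((s.carbon_incubation, "atom_percent_C"),
                         (s.nitrogen_incubation, "atom_percent_N")):
            if inc is None:
                continue
            inc = dataclasses.replace(inc, R_ini=r_ini[inc.element])
            for _, m in sub.iterrows():
                r, clamped = flux_model.enrichment_fraction(
                    inc.R_ini, m[col], inc.R_final
                )
                rec = flux_model.cell_flux(inc, v_bac, r,
                                           roi_id=int(m["roi_id"]),
                                           clamped=clamped)
                rows.append({
                    "treatment": s.treatment, "replicate": s.replicate,
                    "element": inc.element, "substrate": inc.substrate,
                    "roi_id": rec.roi_id, "r": rec.r,
                    "F_mol_per_cell_h": rec.F_mol,
                    "mass_flux_fg_per_cell_h": rec.mass_flux_fg,
                    "clamped": rec.clamped,
                })
    flux_df = pd.DataFrame(rows)
    flux_df.to_csv(out_path, index=False)
    summary = (
        flux_df.groupby(["treatment", "element"])["mass_flux_fg_per_cell_h"]
        .agg(["count", "mean", "std", "median"])
        .reset_index()
    )
    summary.to_csv(config.out_dir / "flux_summary.csv", index=False)
    logger.info("flux: %d per-cell records", len(flux_df))


def stage_stats(config: RunConfig) -> None:
    out_path = config.out_dir / "stats_results.csv"
    if out_path.exists():
        return
    df = _load_measurements(config)
    rows = []
    for col, label in (("delta_C", "d13C"), ("delta_N", "d15N")):
        grouped = stats_tests.GroupedSamples(
            values=df[col].to_numpy(), group=df["treatment"].to_numpy()
        )
        res = stats_tests.van_der_waerden(grouped, method="chisq")
        letters = stats_tests.pairwise_letters(grouped, alpha=config.alpha)
        rows.append({
            "response": label, "test": res.method,
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "letters": json.dumps(letters.letters),
        })
    labeled = df[df["treatment"] != "control"]
    corr = stats_tests.pearson_corr(labeled["delta_C"].to_numpy(),
                                    labeled["delta_N"].to_numpy())
    rows.append({"response": "d13C~d15N", "test": corr.method,
                 "statistic": corr.statistic, "df": corr.df,
                 "p_value": corr.p_value, "letters": ""})
    try:
        anc = stats_tests.ancova_slopes(labeled["delta_C"].to_numpy(),
                                        labeled["delta_N"].to_numpy(),
                                        labeled["treatment"].to_numpy())
        rows.append({"response": "d15N~d13C slopes", "test": anc.method,
                     "statistic": anc.statistic, "df": str(anc.df),
                     "p_value": anc.p_value, "letters": ""})
    except ValueError as exc:
        logger.warning("stats: ANCOVA skipped (%s)", exc)
    pd.DataFrame(rows).to_csv(out_path, index=False)


def stage_community(config: RunConfig) -> None:
    out_path = config.out_dir / "community_rate.json"
    if out_path.exists():
        return
    flux_path = config.out_dir / "fluxes.csv"
    if not flux_path.exists():
        raise PipelineError(
            f"missing artifact {flux_path}; run the 'flux' stage first"
        )
    flux_df = pd.read_csv(flux_path)
    carbon = flux_df[(flux_df["substrate"] == "bicarbonate")
                     & (flux_df["element"] == "C")]
    means = carbon.groupby("treatment")["mass_flux_fg_per_cell_h"].mean()
    light = float(means.get("CO3L", np.nan))
    dark = float(means.get("CO3D", np.nan))
    if np.isnan(light) or np.isnan(dark):
        raise PipelineError("community stage needs CO3L and CO3D flux records")
    rate, floored = flux_model.community_rate(
        light, dark, config.community.cell_density_per_g
    )
    payload = {
        "mean_CO3L_flux_fg_cell_h": light,
        "mean_CO3D_flux_fg_cell_h": dark,
        "cell_density_per_g": config.community.cell_density_per_g,
        "community_rate_gC_per_g_h": rate,
        "floored_at_zero": floored,
        "chamber_rate_gC_per_g_h": flux_model.chamber_to_per_gram(
            config.community.chamber_flux_mgC_m2_h,
            config.community.biofilm_depth_cm,
            config.community.sediment_density_g_cm3,
        ),
    }
    out_path.write_text(json.dumps(payload, indent=2))
    logger.info("community: %.3g gC/g/h", rate)


def stage_fame(config: RunConfig) -> None:
    out_path = config.out_dir / "fame_enrichment.csv"
    if out_path.exists():
        return
    table_path = config.out_dir / "fame_table.csv"
    if table_path.exists():
        records = fame_csia.read_fame_csv(table_path)
    else:
        _, scenario = synthetic_data.paper_preset(seed=config.seed)
        records, truth = synthetic_data.simulate_fame_table(scenario)
        truth.to_csv(config.out_dir / "fame_truth.csv", index=False)
        fame_csia.write_fame_csv(fame_csia.correct_records(records),
                                 table_path)
    fame_csia.correct_records(records)
    table = fame_csia.enrichment_table(records, control_label="control",
                                       alpha=config.alpha)
    table.to_csv(out_path, index=False)


_STAGE_FN = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "flux": stage_flux,
    "stats": stage_stats,
    "community": stage_community,
    "fame": stage_fame,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] = ()) -> int:
    """Run the requested stages in dependency order; returns 0 on success.

    An empty stage list validates the configuration and writes the resolved
    copy without computing anything.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    _write_resolved_config(config)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        logger.info("stage: %s", stage)
        _STAGE_FN[stage](config)
    return 0
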