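"""NanoSIMS ion-count stack I/O, cell segmentation, and ROI quantification.

A measurement is a stack of secondary-ion count images, one plane per raster
rescan, recorded simultaneously on five detectors: ¹²C⁻, ¹³C⁻, ¹²C¹⁴N⁻,
¹²C¹⁵N⁻ and ³²S⁻.  Cells are segmented from the plane-accumulated ¹²C¹⁴N⁻
image (where biomass gives strong, uniform emission) by thresholding,
4-connected component labeling and shape filtering for the coccoid
morphotype; touching cells can optionally be split by watershed.  Per-ROI
isotope ratios are the ratio of summed counts over all pixels and planes —
the maximum-likelihood estimator under Poisson counting, robust at low
per-pixel counts — with the standard counting-error propagation
σ_R/R = sqrt(1/N_rare + 1/N_abundant).

³²S⁻ is carried through I/O but excluded from quantification; in these mats
elemental sulfur escapes the ³²S⁻ detector and sulfur globules appear only
as emission holes inside cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .isotope_core import CARBON, NITROGEN, ratio_to_atom_percent, ratio_to_delta

__all__ = [
    "CHANNELS",
    "IonCountStack",
    "RoiMask",
    "RoiMeasurement",
    "SegmentationParams",
    "load_stack",
    "save_stack",
    "accumulate_planes",
    "segment_cells",
    "measure_rois",
    "measurements_to_frame",
    "write_measurements_csv",
    "load_mask",
    "save_mask",
]

#: Canonical detector order.
CHANNELS = ("12C", "13C", "12C14N", "12C15N", "32S")


@dataclass
class IonCountStack:
    """Multi-channel, multi-plane ion-count raster.

    ``counts`` has shape (n_channels, n_planes, rows, cols) with channel
    order ``channels``.  ``field_size_um`` is the edge length of the square
    analyzed field; ``dwell_ms`` the counting time per pixel.
    """

    counts: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    field_size_um: float = 25.0
    dwell_ms: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-D (channel, plane, row, col)")
        if self.counts.shape[0] != len(self.channels):
            raise ValueError("first axis must match the channel list")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("ion counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("ion counts must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.counts.shape[1]

    @property
    def raster(self) -> int:
        return self.counts.shape[2]

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um / self.raster

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; found {list(self.channels)}"
            ) from None
        return self.counts[i]


@dataclass
class RoiMask:
    """Integer label image: 0 background, k = ROI id (contiguous from 1)."""

    label_image: np.ndarray
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label image must be 2-D")
        labels = np.unique(self.label_image)
        labels = labels[labels > 0]
        if len(labels) and not np.array_equal(labels, np.arange(1, len(labels) + 1)):
            raise ValueError("ROI labels must be contiguous positive integers")
        if self.provenance not in ("automatic", "imported"):
            raise ValueError("provenance must be 'automatic' or 'imported'")

    @property
    def n_rois(self) -> int:
        return int(self.label_image.max(initial=0))


@dataclass
class RoiMeasurement:
    """Summed counts and derived isotope quantities for one ROI."""

    roi_id: int
    n_pixels: int
    counts: dict[str, int]
    R_C: float
    R_N: float
    atom_percent_C: float
    atom_percent_N: float
    delta_C: float          # vs the international standard
    delta_N: float
    delta_C_control: float | None  # vs the control-mean ratio, when given
    delta_N_control: float | None
    err_R_C: float          # 1-sigma Poisson counting error on the ratio
    err_R_N: float
    valid: bool = True
    flag: str = ""


# --- I/O --------------------------------------------------------------------

def save_stack(stack: IonCountStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, channel-major plane order, with
    acquisition metadata in the image description."""
    path = Path(path)
    meta = {
        "channels": list(stack.channels),
        "n_planes": stack.n_planes,
        "field_size_um": stack.field_size_um,
        "dwell_ms": stack.dwell_ms,
    }
    pages = stack.counts.reshape(-1, stack.counts.shape[2], stack.counts.shape[3])
    tifffile.imwrite(path, pages.astype(np.uint32), description=json.dumps(meta))


def _load_tiff(path: Path, sidecar: Mapping | None) -> IonCountStack:
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if sidecar:
        meta = {**dict(sidecar), **meta}
    channels = tuple(meta.get("channels", CHANNELS))
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    n_planes = int(meta.get("n_planes", n_pages // len(channels)))
    if n_planes * len(channels) != n_pages:
        raise ValueError(
            f"{path}: {n_pages} pages do not factor into "
            f"{len(channels)} channels x {n_planes} planes"
        )
    counts = pages.reshape(len(channels), n_planes, *pages.shape[1:])
    return IonCountStack(
        counts=counts,
        channels=channels,
        field_size_um=float(meta.get("field_size_um", 25.0)),
        dwell_ms=float(meta.get("dwell_ms", 1.0)),
    )


def _load_text_dir(path: Path, sidecar: Mapping | None) -> IonCountStack:
    """Per-channel plain-text matrices: ``<channel>_p<plane>.txt`` files in a
    directory, whitespace-delimited integers."""
    meta = dict(sidecar or {})
    channels = tuple(meta.get("channels", CHANNELS))
    per_channel = []
    for ch in channels:
        files = sorted(path.glob(f"{ch}_p*.txt"),
                       key=lambda p: int(p.stem.rsplit("_p", 1)[1]))
        if not files:
            found = sorted({f.name.rsplit("_p", 1)[0] for f in path.glob("*_p*.txt")})
            raise FileNotFoundError(
                f"channel {ch!r} missing under {path}; found channels {found}"
            )
        planes = [np.loadtxt(f) for f in files]
        per_channel.append(np.stack(planes))
    counts = np.stack(per_channel)
    return IonCountStack(
        counts=counts,
        channels=channels,
        field_size_um=float(meta.get("field_size_um", 25.0)),
        dwell_ms=float(meta.get("dwell_ms", 1.0)),
    )


def load_stack(path: str | Path, format: str | None = None,
               sidecar: Mapping | None = None) -> IonCountStack:
    """Load an ion-count stack from multi-page TIFF or a directory of
    per-channel text matrices.

    ``sidecar`` supplies acquisition metadata (channel order, field size,
    plane count) when the file carries none; embedded metadata wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "text" if path.is_dir() else "tiff"
    if format == "tiff":
        return _load_tiff(path, sidecar)
    if format == "text":
        return _load_text_dir(path, sidecar)
    raise ValueError(f"unknown format {format!r}")


def save_mask(mask: RoiMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.label_image.astype(np.uint16))


def load_mask(path: str | Path) -> RoiMask:
    img = tifffile.imread(Path(path))
    return RoiMask(label_image=_relabel(img.astype(np.int32)), provenance="imported")


# --- processing -------------------------------------------------------------

def accumulate_planes(stack: IonCountStack) -> dict[str, np.ndarray]:
    """Pixel-wise integer sum of counts across planes, per channel."""
    return {
        ch: stack.counts[i].sum(axis=0)
        for i, ch in enumerate(stack.channels)
    }


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to contiguous 1..k preserving order."""
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


@dataclass
class SegmentationParams:
    """Knobs for coccoid-cell detection on the accumulated ¹²C¹⁴N⁻ image.

    Area bounds derive from the expected cell diameter: a disc of diameter
    d·(1±diameter_tolerance) sets the admissible pixel-area window.
    Circularity is 4π·area/perimeter² with 1.0 a perfect disc.
    """

    threshold_mode: str = "otsu"       # "otsu" or "fixed"
    threshold_value: float | None = None
    expected_diameter_um: float = 1.67
    diameter_tolerance: float = 0.5
    min_circularity: float = 0.6
    split_touching: bool = False

    def area_bounds_px(self, pixel_size_um: float) -> tuple[float, float]:
        lo_d = self.expected_diameter_um * (1.0 - self.diameter_tolerance)
        hi_d = self.expected_diameter_um * (1.0 + self.diameter_tolerance)
        if lo_d > hi_d or pixel_size_um <= 0:
            raise ValueError("degenerate area bounds")
        to_px = lambda d: np.pi / 4.0 * (d / pixel_size_um) ** 2
        return to_px(lo_d), to_px(hi_d)


def segment_cells(
    cn_image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> RoiMask:
    """Segment coccoid cells from a plane-accumulated ¹²C¹⁴N⁻ image.

    Threshold (Otsu by default), 4-connected components, then an area window
    around the expected cell diameter and a circularity floor to reject
    debris and filaments.  With ``split_touching`` a distance-transform
    watershed separates merged cells before filtering.  A blank image yields
    an empty mask, not an error.
    """
    if params is None:
        params = SegmentationParams()
    cn_image = np.asarray(cn_image)
    if (cn_image < 0).any():
        raise ValueError("count image must be non-negative")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    min_area, max_area = params.area_bounds_px(pixel_size_um)

    if cn_image.max() == 0:
        return RoiMask(np.zeros(cn_image.shape, dtype=np.int32))

    if params.threshold_mode == "fixed":
        if params.threshold_value is None:
            raise ValueError("fixed threshold mode requires threshold_value")
        thr = params.threshold_value
    elif params.threshold_mode == "otsu":
        thr = threshold_otsu(cn_image)
    else:
        raise ValueError(f"unknown threshold mode {params.threshold_mode!r}")

    binary = cn_image > thr
    if not binary.any():
        return RoiMask(np.zeros(cn_image.shape, dtype=np.int32))
    # sulfur globules appear as zero-emission holes inside cells; fill them
    # so cells are measured as solid discs
    binary = ndimage.binary_fill_holes(binary)

    if params.split_touching:
        dist = ndimage.distance_transform_edt(binary)
        min_sep = max(1, int(0.5 * params.expected_diameter_um / pixel_size_um))
        peaks = peak_local_max(dist, min_distance=min_sep, labels=binary,
                               exclude_border=False)
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=binary, connectivity=1)
    else:
        labels = cc_label(binary, connectivity=1)

    keep = np.zeros(labels.max() + 1, dtype=bool)
    for prop in regionprops(labels):
        if not min_area <= prop.area <= max_area:
            continue
        if prop.perimeter == 0:
            continue
        circularity = 4.0 * np.pi * prop.area / prop.perimeter**2
        if circularity < params.min_circularity:
            continue
        keep[prop.label] = True
    filtered = np.where(keep[labels], labels, 0)
    return RoiMask(_relabel(filtered))


def _poisson_ratio_error(n_rare: float, n_abundant: float) -> float:
    r = n_rare / n_abundant
    return r * np.sqrt(1.0 / n_rare + 1.0 / n_abundant)


def measure_rois(
    stack: IonCountStack,
    mask: RoiMask,
    control_ratios: Mapping[str, float] | None = None,
) -> list[RoiMeasurement]:
    """Quantify isotope ratios per ROI.

    Counts are summed over all pixels of the ROI and all planes before the
    ratio is taken (ratio of sums, not mean of per-pixel ratios).  δ values
    are reported against the international standards and, when
    ``control_ratios`` gives the control-mean ¹³C/¹²C and ¹⁵N/¹⁴N ratios
    (keys ``"C"``, ``"N"``), also against the control.  A ROI with zero
    abundant-isotope counts is returned flagged invalid.
    """
    if mask.label_image.shape != stack.counts.shape[2:]:
        raise ValueError("mask and stack raster dimensions differ")
    accumulated = accumulate_planes(stack)
    out: list[RoiMeasurement] = []
    label_img = mask.label_image
    for roi_id in range(1, mask.n_rois + 1):
        sel = label_img == roi_id
        sums = {ch: int(accumulated[ch][sel].sum()) for ch in stack.channels}
        n12, n13 = sums["12C"], sums["13C"]
        n14, n15 = sums["12C14N"], sums["12C15N"]
        if n12 == 0 or n14 == 0:
            out.append(RoiMeasurement(
                roi_id=roi_id, n_pixels=int(sel.sum()), counts=sums,
                R_C=np.nan, R_N=np.nan, atom_percent_C=np.nan,
                atom_percent_N=np.nan, delta_C=np.nan, delta_N=np.nan,
                delta_C_control=None, delta_N_control=None,
                err_R_C=np.nan, err_R_N=np.nan,
                valid=False, flag="zero abundant-isotope counts",
            ))
            continue
        r_c = n13 / n12
        r_n = n15 / n14
        dc_ctrl = dn_ctrl = None
        if control_ratios is not None:
            dc_ctrl = (r_c / control_ratios["C"] - 1.0) * 1000.0
            dn_ctrl = (r_n / control_ratios["N"] - 1.0) * 1000.0
        out.append(RoiMeasurement(
            roi_id=roi_id,
            n_pixels=int(sel.sum()),
            counts=sums,
            R_C=r_c,
            R_N=r_n,
            atom_percent_C=ratio_to_atom_percent(r_c),
            atom_percent_N=ratio_to_atom_percent(r_n),
            delta_C=ratio_to_delta(r_c, CARBON),
            delta_N=ratio_to_delta(r_n, NITROGEN),
            delta_C_control=dc_ctrl,
            delta_N_control=dn_ctrl,
            err_R_C=_poisson_ratio_error(n13, n12) if n13 > 0 else np.nan,
            err_R_N=_poisson_ratio_error(n15, n14) if n15 > 0 else np.nan,
        ))
    return out


def measurements_to_frame(measurements: Sequence[RoiMeasurement]) -> pd.DataFrame:
    """One row per ROI with counts, ratios, atom% and δ columns."""
    rows = []
    for m in measurements:
        row = {"roi_id": m.roi_id, "n_pixels": m.n_pixels}
        row.update({f"counts_{ch}": n for ch, n in m.counts.items()})
        row.update(
            R_C=m.R_C, R_N=m.R_N,
            atom_percent_C=m.atom_percent_C, atom_percent_N=m.atom_percent_N,
            delta_C=m.delta_C, delta_N=m.delta_N,
            delta_C_control=m.delta_C_control, delta_N_control=m.delta_N_control,
            err_R_C=m.err_R_C, err_R_N=m.err_R_N,
            valid=m.valid, flag=m.flag,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_measurements_csv(measurements: Sequence[RoiMeasurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)
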