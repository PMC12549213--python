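"""Synthetic two-channel fields with known ground truth.

Emulates the assay's imaging statistics — DAPI-like nuclei, a diffuse
cytoplasmic ASC background, and bright punctate specks — so that every
stage of the pipeline can be tested against planted truth without any
image downloads. One speck per positive cell (inflammasome activation
nucleates a single supramolecular aggregate); extracellular specks are
planted separately to exercise the intracellular filter.

The generator is fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import gaussian

from .io import ImageField


class PackingError(RuntimeError):
    """Requested nuclei could not be placed without overlap."""


def tuned_detection_params() -> "DetectionParams":
    """Detection operating point for the synthetic imaging conditions.

    The assay procedure tunes the absolute/relative intensity cut-offs by
    inspecting the distribution of blob local maxima, placing the cut-off
    in the valley between the diffuse-background mode and the speck mode.
    For fields generated with the defaults above, background local maxima
    sit below ~0.15 of full scale and speck maxima near ~0.7, so an
    absolute cut-off of 0.3 separates the modes with wide margin.
    """
    from .detection import DetectionParams

    return DetectionParams(abs_threshold=0.3)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field.

    Defaults mirror the assay's acquisition: a 1392 x 1040 camera frame
    at ~0.5 um/px with on average 370 nuclei of ~6 um radius (12 px),
    diffuse cytoplasmic ASC staining and compact (~2 px sigma) specks
    well above the read noise.
    """

    shape: Tuple[int, int] = (1040, 1392)
    n_cells: int = 370
    cell_radius_mean: float = 12.0
    cell_radius_sd: float = 3.0
    speck_fraction: float = 0.15
    n_extracellular_specks: int = 2
    speck_sigma_px: float = 2.0
    speck_amplitude: float = 0.6
    nuclear_amplitude: float = 0.7
    cytoplasm_background: float = 0.08
    noise_sd: float = 0.02
    cell_count_cv: float = 0.0
    bit_depth: int = 16
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.speck_fraction <= 1:
            raise ValueError("speck_fraction must be in [0, 1]")
        if not 0 < self.speck_amplitude <= 1:
            raise ValueError("speck_amplitude must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted objects for one field; self-consistent by construction."""

    nuclei: List[Tuple[float, float, float]] = dc_field(default_factory=list)  # (row, col, radius)
    speck_positions: List[Tuple[float, float, bool]] = dc_field(default_factory=list)  # (row, col, intracellular)

    @property
    def n_cells(self) -> int:
        return len(self.nuclei)

    @property
    def n_intracellular(self) -> int:
        return sum(1 for *_, intra in self.speck_positions if intra)

    @property
    def true_pct_asc(self) -> float:
        if not self.nuclei:
            return 0.0
        return 100.0 * self.n_intracellular / self.n_cells


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator) -> List[Tuple[float, float, float]]:
    """Rejection-sample non-overlapping nucleus centres, fully in bounds."""
    nuclei: List[Tuple[float, float, float]] = []
    rows, cols = spec.shape
    max_tries = 200 * max(spec.n_cells, 1)
    tries = 0
    gap = 4.0  # min clearance between nucleus rims, px
    while len(nuclei) < spec.n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {spec.n_cells} nuclei of radius "
                f"~{spec.cell_radius_mean} px in a {spec.shape} field"
            )
        tries += 1
        radius = float(
            np.clip(
                rng.normal(spec.cell_radius_mean, spec.cell_radius_sd),
                0.5 * spec.cell_radius_mean,
                2.0 * spec.cell_radius_mean,
            )
        )
        margin = radius + 3
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        if all(
            np.hypot(r - r0, c - c0) >= radius + rad0 + gap
            for r0, c0, rad0 in nuclei
        ):
            nuclei.append((r, c, radius))
    return nuclei


def _add_gaussian_spot(
    img: np.ndarray, row: float, col: float, sigma: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian punctum in place (local window only)."""
    half = int(np.ceil(4 * sigma))
    r0, c0 = int(round(row)), int(round(col))
    rows, cols = img.shape
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, rows)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, cols)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)
    )


def _draw_disk(img: np.ndarray, row: float, col: float, radius: float, level: float) -> None:
    """Set a hard disk to at least `level` in place."""
    half = int(np.ceil(radius)) + 1
    r0, c0 = int(round(row)), int(round(col))
    rows, cols = img.shape
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, rows)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, cols)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    disk = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    region = img[rlo:rhi, clo:chi]
    region[disk] = np.maximum(region[disk], level)


def generate_field(spec: SyntheticSpec, field_id: str = "synthetic") -> Tuple[ImageField, GroundTruth]:
    """Render one two-channel field and its ground truth.

    Nuclear channel: soft-edged bright disks plus Gaussian read noise.
    ASC channel: a diffuse cytoplasmic disc around every nucleus at the
    background level, one bright Gaussian punctum inside each
    speck-positive nucleus, extracellular puncta on free background,
    plus read noise. Identical spec (including seed) gives bit-identical
    rasters.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    nuclei = _place_nuclei(spec, rng)
    truth = GroundTruth(nuclei=list(nuclei))

    nuclear = np.zeros(spec.shape, dtype=np.float64)
    asc = np.zeros(spec.shape, dtype=np.float64)

    for r, c, radius in nuclei:
        level = float(np.clip(rng.normal(spec.nuclear_amplitude, 0.05), 0.3, 1.0))
        _draw_disk(nuclear, r, c, radius, level)
        _draw_disk(asc, r, c, radius * 1.8, spec.cytoplasm_background)

    # one speck per positive cell, planted well inside the nucleus so the
    # nucleus-based intracellular test is unambiguous
    n_positive = int(round(spec.speck_fraction * len(nuclei)))
    positive_idx = rng.choice(len(nuclei), size=n_positive, replace=False) if n_positive else []
    for i in sorted(positive_idx):
        r, c, radius = nuclei[i]
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.3 * radius)
        sr, sc = r + rho * np.sin(theta), c + rho * np.cos(theta)
        _add_gaussian_spot(asc, sr, sc, spec.speck_sigma_px, spec.speck_amplitude)
        truth.speck_positions.append((sr, sc, True))

    # extracellular specks on background, clear of every cytoplasm disc
    # and of each other
    placed = 0
    tries = 0
    margin = 4 * spec.speck_sigma_px + 2
    while placed < spec.n_extracellular_specks and tries < 5000:
        tries += 1
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        if any(np.hypot(r - r0, c - c0) < rad0 * 1.8 + 8 for r0, c0, rad0 in nuclei):
            continue
        if any(np.hypot(r - sr, c - sc) < 12 for sr, sc, _ in truth.speck_positions):
            continue
        _add_gaussian_spot(asc, r, c, spec.speck_sigma_px, spec.speck_amplitude)
        truth.speck_positions.append((r, c, False))
        placed += 1
    if placed < spec.n_extracellular_specks:
        raise PackingError("could not place extracellular specks on free background")

    # soften nucleus edges, then add read noise and quantise
    nuclear = gaussian(nuclear, sigma=1.5, preserve_range=True)
    nuclear += rng.normal(0.0, spec.noise_sd, spec.shape)
    asc += rng.normal(0.0, spec.noise_sd, spec.shape)
    lim = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    field = ImageField(
        field_id=field_id,
        nuclear=np.round(np.clip(nuclear, 0, 1) * lim).astype(dtype),
        asc=np.round(np.clip(asc, 0, 1) * lim).astype(dtype),
        bit_depth=spec.bit_depth,
        pixel_size_um=spec.pixel_size_um,
    )
    return field, truth


def derive_field_seed(base_seed: int, index: int) -> int:
    """Deterministic per-field seed, kept within 31 bits."""
    return (base_seed * 100003 + 7919 * index + 1) % (2**31)


def generate_sample(
    spec: SyntheticSpec,
    n_fields: int = 5,
    sample_id: str = "synthetic",
    condition: str = "stimulated",
) -> Tuple[List[Tuple[ImageField, GroundTruth]], pd.DataFrame]:
    """Generate the replicate fields of one sample plus manifest rows.

    Fields are independent draws with per-field seeds derived from the
    base seed; the manifest mirrors the CSV schema used for real data
    (paths are filled in by :func:`write_sample`).

    With ``cell_count_cv`` > 0, the number of nuclei varies between the
    replicate fields of a sample (n_cells is then the mean); real
    cytospin fields show large density variation, roughly a 37%
    coefficient of variation (370 +/- 136 cells per frame).
    """
    fields = []
    rows = []
    for i in range(n_fields):
        field_seed = derive_field_seed(spec.seed, i)
        n_cells_i = spec.n_cells
        if spec.cell_count_cv > 0 and spec.n_cells > 0:
            draw = np.random.default_rng(field_seed).normal(
                spec.n_cells, spec.cell_count_cv * spec.n_cells
            )
            n_cells_i = int(np.clip(round(draw), 1, 2 * spec.n_cells))
        fspec = SyntheticSpec(
            **{**spec.__dict__, "seed": field_seed, "n_cells": n_cells_i}
        )
        field_id = f"{sample_id}_f{i + 1}"
        fields.append(generate_field(fspec, field_id=field_id))
        rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "field_id": field_id,
                "nuclear_path": f"{field_id}_nuclear.tif",
                "asc_path": f"{field_id}_asc.tif",
            }
        )
    return fields, pd.DataFrame(rows)


def write_sample(
    fields_and_truth: List[Tuple[ImageField, GroundTruth]],
    manifest: pd.DataFrame,
    out_dir,
) -> pd.DataFrame:
    """Write TIFFs, manifest.csv and truth.csv; returns the path-resolved manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    truth_rows = []
    for (field, truth), (_, row) in zip(fields_and_truth, manifest.iterrows()):
        npath = out_dir / row["nuclear_path"]
        apath = out_dir / row["asc_path"]
        tifffile.imwrite(npath, field.nuclear)
        tifffile.imwrite(apath, field.asc)
        truth_rows.append(
            {
                "field_id": field.field_id,
                "n_cells": truth.n_cells,
                "n_specks_intracellular": truth.n_intracellular,
                "n_specks_total": len(truth.speck_positions),
                "true_pct_asc": truth.true_pct_asc,
            }
        )
    manifest["nuclear_path"] = [str(out_dir / p) for p in manifest["nuclear_path"]]
    manifest["asc_path"] = [str(out_dir / p) for p in manifest["asc_path"]]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest
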