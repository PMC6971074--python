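"""Ground-truthed synthetic tissue: cell tables and multi-round image stacks.

The generator emulates the statistical structure the downstream analysis
assumes: a mixture of immune phenotypes (plus marker-negative tumor
cells) with Gaussian marker expression truncated at zero, hard-disk
non-overlapping cell placement under a configurable spatial model,
round-to-round rigid stage shifts, additive autofluorescence background,
and — crucially for the dual-mask segmentation design — macrophage
phenotypes whose nuclear DAPI signal is dimmed by a per-phenotype
factor, so that a nuclei-only mask undercounts them while the combined
leukocyte-lineage ("targeted") mask does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .model import MarkerPanel, MultiplexImage, PlacementError, ValidationError

__all__ = [
    "PhenotypeSpec",
    "CSR",
    "Clustered",
    "Avoidance",
    "TissueSpec",
    "generate_cell_table",
    "render_image",
    "default_phenotypes",
    "default_tissue_spec",
    "DEFAULT_MARKERS",
    "POSITIVE_MEAN",
    "NEGATIVE_MEAN",
]

# Non-DAPI markers of the default synthetic panel. Sixteen channels
# (with DAPI) suffice to exercise every default cell-type rule.
DEFAULT_MARKERS = (
    "CD45", "CD3", "CD4", "CD8", "FOXP3", "TCF7", "PD1", "CD20",
    "CD16", "CD68", "CD163", "LYZ", "VISTA", "GranzymeB", "Granulysin",
)

POSITIVE_MEAN, POSITIVE_SD = 8.0, 1.5
NEGATIVE_MEAN, NEGATIVE_SD = 0.5, 0.3
SPOTTY_MEAN, SPOTTY_SD = 1.5, 0.8  # sub-threshold "spotty" lineage staining


@dataclass(frozen=True)
class PhenotypeSpec:
    """Marker profile and geometry of one simulated cell type."""

    name: str
    marker_means: dict
    marker_sds: dict
    abundance: float
    dapi_intensity_factor: float = 1.0
    radius_um: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.dapi_intensity_factor <= 1:
            raise ValidationError(f"{self.name}: dapi_intensity_factor must be in (0, 1]")
        if any(s < 0 for s in self.marker_sds.values()):
            raise ValidationError(f"{self.name}: negative marker sd")
        if self.radius_um <= 0:
            raise ValidationError(f"{self.name}: radius_um must be > 0")
        if set(self.marker_means) != set(self.marker_sds):
            raise ValidationError(f"{self.name}: marker_means/marker_sds keys differ")


@dataclass(frozen=True)
class CSR:
    """Complete spatial randomness (uniform placement)."""


@dataclass(frozen=True)
class Clustered:
    """One cell type aggregates around Poisson parent centers; the rest is CSR."""

    cell_type: str
    n_parents: int = 10
    cluster_sd_um: float = 50.0


@dataclass(frozen=True)
class Avoidance:
    """Hard-core inhibition between two named cell types."""

    type_a: str
    type_b: str
    min_dist_um: float = 120.0


@dataclass(frozen=True)
class TissueSpec:
    """Full description of a simulated tissue field."""

    phenotypes: tuple
    n_cells: int
    field_um: tuple = (1000.0, 1000.0)
    spatial_model: object = field(default_factory=CSR)
    af_level: float = 1.0
    noise_sd: float = 0.5
    shift_per_round: tuple | None = None
    dapi_mean: float = 10.0
    dapi_sd: float = 1.0
    min_gap_um: float = 4.0
    pixel_size_um: float = 1.0
    markers_per_round: int = 3
    case_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotypes", tuple(self.phenotypes))
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        total = sum(p.abundance for p in self.phenotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"phenotype abundances sum to {total}, expected 1")
        keys = set(self.phenotypes[0].marker_means)
        for p in self.phenotypes[1:]:
            if set(p.marker_means) != keys:
                raise ValidationError(f"{p.name}: marker set differs across phenotypes")

    @property
    def markers(self) -> tuple[str, ...]:
        """Panel order: DAPI first, then the phenotype marker keys."""
        return ("DAPI",) + tuple(self.phenotypes[0].marker_means)

    @property
    def panel(self) -> MarkerPanel:
        """Panel of the aligned, autofluorescence-subtracted stack."""
        return MarkerPanel(
            markers=self.markers,
            pixel_size_um=self.pixel_size_um,
            rounds=1,
            dapi_channel_per_round={1: 0},
        )


def _profile(positive: Sequence[str] = (), spotty: Sequence[str] = ()) -> tuple[dict, dict]:
    means = {m: NEGATIVE_MEAN for m in DEFAULT_MARKERS}
    sds = {m: NEGATIVE_SD for m in DEFAULT_MARKERS}
    for m in spotty:
        means[m], sds[m] = SPOTTY_MEAN, SPOTTY_SD
    for m in positive:
        means[m], sds[m] = POSITIVE_MEAN, POSITIVE_SD
    return means, sds


def default_phenotypes(tumor_fraction: float = 0.5) -> tuple[PhenotypeSpec, ...]:
    """The default ten-phenotype mixture: nine immune types plus tumor.

    Immune abundances mirror a macrophage-dominated sarcoma infiltrate
    (TAM the largest group, histiocytes next, lymphocytes a minority);
    they are repo-defined synthetic numbers, not measured values. The
    macrophage types carry ``dapi_intensity_factor`` well below 1 so
    nuclear thresholding misses them, as real chromatin-poor
    macrophages are missed.
    """
    immune = 1.0 - tumor_fraction
    # relative abundances within the immune compartment
    rel = {
        "CD4_T": 0.08, "CD8_T": 0.11, "NK": 0.03, "B": 0.02,
        "TAM": 0.38, "Histiocyte": 0.20, "Phagocyte": 0.05,
        "InflammatoryMonocyte": 0.04, "MonoMac_undefined": 0.09,
    }
    defs = {
        "CD4_T": dict(positive=("CD45", "CD3", "CD4", "FOXP3")),
        "CD8_T": dict(positive=("CD45", "CD3", "CD8", "PD1")),
        "NK": dict(positive=("CD45", "GranzymeB", "Granulysin")),
        "B": dict(positive=("CD45", "CD20")),
        "TAM": dict(positive=("CD45", "CD16", "CD68", "CD163"), dapi=0.2),
        "Histiocyte": dict(positive=("CD45", "CD68", "CD163"), dapi=0.25),
        "Phagocyte": dict(positive=("CD45", "CD68"), dapi=0.3),
        "InflammatoryMonocyte": dict(positive=("CD45", "LYZ", "VISTA"), dapi=0.9),
        "MonoMac_undefined": dict(
            positive=("CD45",), spotty=("CD68", "CD163", "LYZ"), dapi=0.6
        ),
    }
    phens = []
    for name, d in defs.items():
        means, sds = _profile(d.get("positive", ()), d.get("spotty", ()))
        phens.append(
            PhenotypeSpec(
                name=name, marker_means=means, marker_sds=sds,
                abundance=immune * rel[name],
                dapi_intensity_factor=d.get("dapi", 1.0),
                radius_um=3.5 if name in ("CD4_T", "CD8_T", "NK", "B") else 4.5,
            )
        )
    if tumor_fraction > 0:
        means, sds = _profile()
        phens.append(
            PhenotypeSpec(
                name="Tumor", marker_means=means, marker_sds=sds,
                abundance=tumor_fraction, radius_um=5.0,
            )
        )
    return tuple(phens)


def default_tissue_spec(n_cells: int = 5000, density_per_mm2: float = 1500.0,
                        **kwargs) -> TissueSpec:
    """Default field: cell count at a realistic tumor cellularity."""
    side = math.sqrt(n_cells / density_per_mm2) * 1000.0
    return TissueSpec(
        phenotypes=default_phenotypes(),
        n_cells=n_cells,
        field_um=(side, side),
        **kwargs,
    )


# ------------------------------------------------------------- sampling

def _sample_positions(spec: TissueSpec, radii: np.ndarray, names: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Sequential hard-disk placement under the spec's spatial model."""
    w, h = spec.field_um
    n = len(radii)
    pos = np.empty((n, 2))  # (x, y) um
    model = spec.spatial_model
    parents = None
    if isinstance(model, Clustered):
        parents = rng.uniform([0, 0], [w, h], size=(model.n_parents, 2))
    max_tries = 20_000
    for i in range(n):
        margin = radii[i] + spec.pixel_size_um
        for attempt in range(max_tries):
            if parents is not None and names[i] == model.cell_type:
                c = parents[rng.integers(len(parents))]
                cand = c + rng.normal(0.0, model.cluster_sd_um, 2)
                if not (margin <= cand[0] <= w - margin and margin <= cand[1] <= h - margin):
                    continue
            else:
                cand = rng.uniform([margin, margin], [w - margin, h - margin])
            if i:
                d = np.hypot(pos[:i, 0] - cand[0], pos[:i, 1] - cand[1])
                if np.any(d < radii[:i] + radii[i] + spec.min_gap_um):
                    continue
                if isinstance(model, Avoidance) and names[i] in (model.type_a, model.type_b):
                    other = model.type_b if names[i] == model.type_a else model.type_a
                    sel = names[:i] == other
                    if np.any(d[sel] < model.min_dist_um):
                        continue
            pos[i] = cand
            break
        else:
            raise ValidationError(
                f"could not place cell {i + 1}/{n}: field too crowded for the "
                f"hard-disk / avoidance constraints"
            )
    return pos


def generate_cell_table(spec: TissueSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a ground-truthed single-cell table from the tissue spec.

    Returns ``(table, truth)``: the table is the standard single-cell
    format (cell_id, case_id, centroid, area, mean intensity per
    marker); the truth frame carries the generating type and true mean
    expression per cell. Deterministic for fixed ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    phens = spec.phenotypes
    k = len(phens)
    idx = rng.choice(k, size=spec.n_cells, p=[p.abundance for p in phens])
    names = np.array([phens[j].name for j in idx])
    radii = np.array([phens[j].radius_um for j in idx])
    pos = _sample_positions(spec, radii, names, rng)

    markers = spec.markers  # DAPI first
    n = spec.n_cells
    means = np.empty((n, len(markers)))
    sds = np.empty((n, len(markers)))
    dapi_factor = np.array([phens[j].dapi_intensity_factor for j in idx])
    means[:, 0] = spec.dapi_mean * dapi_factor
    sds[:, 0] = spec.dapi_sd
    for c, m in enumerate(markers[1:], start=1):
        means[:, c] = [phens[j].marker_means[m] for j in idx]
        sds[:, c] = [phens[j].marker_sds[m] for j in idx]
    expr = np.maximum(0.0, rng.normal(means, sds))

    table = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "case_id": spec.case_id,
        "x_um": pos[:, 0],
        "y_um": pos[:, 1],
        "area_um2": np.pi * radii**2,
    })
    for c, m in enumerate(markers):
        table[m] = expr[:, c]

    truth = pd.DataFrame({
        "cell_id": table["cell_id"],
        "true_type": names,
        "x_um": pos[:, 0],
        "y_um": pos[:, 1],
    })
    for c, m in enumerate(markers):
        truth[m] = means[:, c]
    return table, truth


# ------------------------------------------------------------- rendering

def _round_panels(spec: TissueSpec) -> list[tuple[str, ...]]:
    """Split non-DAPI markers into per-round channel lists (DAPI first in
    each round; the blank autofluorescence channel 'AF' ends the last round)."""
    non_dapi = list(spec.markers[1:])
    per = spec.markers_per_round
    groups = [non_dapi[i:i + per] for i in range(0, len(non_dapi), per)] or [[]]
    rounds = [("DAPI", *g) for g in groups]
    if spec.af_level > 0:
        rounds[-1] = rounds[-1] + ("AF",)
    return rounds


def _translate(stack: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill, over the trailing two axes."""
    out = np.zeros_like(stack)
    h, w = stack.shape[-2:]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[..., yd, xd] = stack[..., ys, xs]
    return out


def render_image(table: pd.DataFrame, truth: pd.DataFrame, spec: TissueSpec,
                 seed: int) -> list[MultiplexImage]:
    """Rasterize the cell table into per-round image stacks.

    Each cell is a uniform disk of its phenotype radius painted with the
    cell's tabulated intensities (the DAPI value already carries the
    per-phenotype dim-chromatin factor). Per-round stacks are offset by
    ``shift_per_round``, non-DAPI channels gain the flat
    autofluorescence level, and everything gets zero-truncated Gaussian
    read noise.
    """
    px = spec.pixel_size_um
    shape = (int(round(spec.field_um[1] / px)), int(round(spec.field_um[0] / px)))
    rng = np.random.default_rng(seed)
    radii = truth["true_type"].map(
        {p.name: p.radius_um for p in spec.phenotypes}).to_numpy()

    base = {m: np.zeros(shape) for m in spec.markers}
    for i in range(len(table)):
        cy, cx = table["y_um"].iat[i] / px, table["x_um"].iat[i] / px
        r = radii[i] / px
        if cy - r < -0.5 or cx - r < -0.5 or cy + r > shape[0] - 0.5 or cx + r > shape[1] - 0.5:
            raise PlacementError(f"cell {table['cell_id'].iat[i]} outside the field")
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        for m in spec.markers:
            base[m][rr, cc] = table[m].iat[i]

    round_markers = _round_panels(spec)
    shifts = spec.shift_per_round or tuple((0, 0) for _ in round_markers)
    if len(shifts) != len(round_markers):
        raise ValidationError(
            f"shift_per_round has {len(shifts)} entries for {len(round_markers)} rounds"
        )
    images = []
    for r_idx, markers in enumerate(round_markers):
        chans = []
        for m in markers:
            if m == "AF":
                ch = np.full(shape, float(spec.af_level))
            elif m == "DAPI":
                ch = base["DAPI"].copy()
            else:
                ch = base[m] + spec.af_level
            chans.append(ch)
        stack = np.stack(chans)
        dy, dx = shifts[r_idx]
        stack = _translate(stack, int(dy), int(dx))
        if spec.noise_sd > 0:
            stack = stack + rng.normal(0.0, spec.noise_sd, stack.shape)
        stack = np.maximum(stack, 0.0)
        panel = MarkerPanel(
            markers=markers, pixel_size_um=px, rounds=1,
            dapi_channel_per_round={1: 0},
        )
        images.append(MultiplexImage(channels=stack, panel=panel))
    return images
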