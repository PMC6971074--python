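"""End-to-end orchestration of the synthetic / image analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import phenotype as ph
from .features import density, quantify
from .model import MultiplexImage
from .neighborhood import NeighborhoodParams, interaction_test
from .prep import register_rounds, subtract_autofluorescence
from .segment import (SegmentationParams, compare_mask_yield,
                      make_nuclear_mask, make_targeted_mask)
from .synth import TissueSpec, default_tissue_spec, generate_cell_table, render_image


@dataclass
class CaseResult:
    """Everything one simulated case produces along the pipeline."""

    truth: pd.DataFrame
    image: MultiplexImage
    nuclear_mask: object
    targeted_mask: object
    yield_ratio: float
    cells: pd.DataFrame          # typed, normalized single-cell table
    raw_cells: pd.DataFrame      # as quantified from the image
    profiles: list
    cluster_map: dict
    composition: dict
    state: ph.CaseTCellState
    lymphocyte_density: float
    neighborhood: pd.DataFrame | None = None


def prepare_rounds(rounds, af_channel: str = "AF", af_scale: float = 1.0):
    """Register staining rounds and subtract the blank channel if present."""
    image, reg = register_rounds(rounds)
    if af_channel in image.panel.markers:
        image = subtract_autofluorescence(image, af_channel, af_scale)
    return image, reg


def run_case(spec: TissueSpec | None = None, seed: int = 0,
             seg_params: SegmentationParams | None = None,
             k: int = 30, resolution: float = 0.1,
             neighborhood_params: NeighborhoodParams | None = None,
             run_neighborhood: bool = False) -> CaseResult:
    """Simulate one case and run the full analysis on its rendered images."""
    spec = spec or default_tissue_spec()
    table, truth = generate_cell_table(spec, seed)
    rounds = render_image(table, truth, spec, seed + 1)
    image, _ = prepare_rounds(rounds)
    nuclear = make_nuclear_mask(image, seg_params)
    targeted = make_targeted_mask(image, params=seg_params)
    raw_cells = quantify(image, targeted, case_id=spec.case_id)
    area_mm2 = spec.field_um[0] * spec.field_um[1] / 1e6
    normalized = ph.normalize(raw_cells)
    labels = ph.cluster_phenograph(normalized, k=k, seed=seed, resolution=resolution)
    cells, profiles, cluster_map = ph.assign_cell_types(normalized, labels)
    comp = ph.composition(cells)
    state = ph.classify_tcell_state(cells, area_mm2)
    nbr = interaction_test(cells, neighborhood_params) if run_neighborhood else None
    return CaseResult(
        truth=truth, image=image, nuclear_mask=nuclear, targeted_mask=targeted,
        yield_ratio=compare_mask_yield(nuclear, targeted),
        cells=cells, raw_cells=raw_cells, profiles=profiles,
        cluster_map=cluster_map, composition=comp, state=state,
        lymphocyte_density=state.lymphocyte_density_per_mm2,
        neighborhood=nbr,
    )


def run_table_only(spec: TissueSpec | None = None, seed: int = 0,
                   k: int = 30, resolution: float = 0.1):
    """Phenotyping chain on the generated table, bypassing imaging.

    Returns ``(typed_cells, truth, profiles, cluster_map)``.
    """
    spec = spec or default_tissue_spec()
    table, truth = generate_cell_table(spec, seed)
    normalized = ph.normalize(table)
    labels = ph.cluster_phenograph(normalized, k=k, seed=seed, resolution=resolution)
    cells, profiles, cluster_map = ph.assign_cell_types(normalized, labels)
    return cells, truth, profiles, cluster_map
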