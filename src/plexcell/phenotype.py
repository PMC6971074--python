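"""Phenotyping: normalization, graph clustering, cluster profiling,
rule-based nine-type classification and per-case T-cell state calling.

The clustering step is Phenograph-style: an exact Euclidean kNN graph on
the normalized marker space, edges re-weighted by the Jaccard overlap of
the two endpoints' neighbor sets, then seeded Louvain modularity
optimization. A cluster is called a given cell type when, for every
required marker, at least a third of its cells are positive (normalized
intensity above threshold) and every forbidden marker stays below that
third — the rule engine mirrors how phenocluster heatmaps are read.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import NearestNeighbors

from .io import BASE_COLUMNS
from .model import ValidationError

__all__ = [
    "CELL_TYPES", "LYMPHOID_TYPES", "TCELL_STATES", "UNASSIGNED",
    "NormalizationParams", "normalize",
    "cluster_phenograph",
    "ClusterProfile", "profile_clusters",
    "CellTypeRule", "load_rules", "classify_cluster", "RuleTieError",
    "assign_cell_types",
    "CaseTCellState", "classify_tcell_state",
    "composition",
    "marker_columns",
]

CELL_TYPES = (
    "CD4_T", "CD8_T", "NK", "B", "TAM", "Histiocyte", "Phagocyte",
    "InflammatoryMonocyte", "MonoMac_undefined",
)
LYMPHOID_TYPES = ("CD4_T", "CD8_T", "NK")
TCELL_STATES = ("T_ex-acute", "T_ex-chronic", "T_ex-mixed", "Deserted")
UNASSIGNED = "Unassigned"

POSITIVITY_FRACTION = 1.0 / 3.0  # "a third or more of the cells"

_NON_MARKER = set(BASE_COLUMNS) | {"cluster_id", "cell_type"}


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _NON_MARKER]


# ---------------------------------------------------------- normalization

@dataclass(frozen=True)
class NormalizationParams:
    """Clip each marker above ``clip_percentile`` then z-score, optionally
    after an arcsinh(x / cofactor) variance-stabilizing transform."""

    clip_percentile: float = 99.0
    arcsinh_cofactor: float | None = None

    def __post_init__(self) -> None:
        if not 90 < self.clip_percentile <= 100:
            raise ValueError("clip_percentile must be in (90, 100]")
        if self.arcsinh_cofactor is not None and self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be > 0")


def normalize(table: pd.DataFrame, markers: Sequence[str] | None = None,
              params: NormalizationParams | None = None) -> pd.DataFrame:
    """Per-marker clip + (arcsinh) + z-score; returns a copy.

    A constant marker column cannot be scaled: it becomes all zeros with
    a warning.
    """
    if len(table) < 2:
        raise ValueError("normalization needs at least 2 cells")
    params = params or NormalizationParams()
    markers = list(markers) if markers is not None else marker_columns(table)
    out = table.copy()
    for m in markers:
        x = out[m].to_numpy(dtype=float)
        hi = np.percentile(x, params.clip_percentile)
        x = np.minimum(x, hi)
        if params.arcsinh_cofactor is not None:
            x = np.arcsinh(x / params.arcsinh_cofactor)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"marker {m!r} is constant; normalized to zeros")
            out[m] = 0.0
        else:
            out[m] = (x - x.mean()) / sd
    return out


# ------------------------------------------------------------- clustering

def cluster_phenograph(table: pd.DataFrame, markers: Sequence[str] | None = None,
                       k: int = 30, seed: int = 0,
                       resolution: float = 0.1) -> np.ndarray:
    """kNN-Jaccard graph + seeded Louvain; labels 1..C, deterministic.

    ``resolution`` is deliberately coarse by default: modularity at unit
    resolution shatters large homogeneous phenogroups into arbitrary
    sub-communities, while lineage-level groups are what the downstream
    rule engine consumes.
    """
    markers = list(markers) if markers is not None else marker_columns(table)
    x = table[markers].to_numpy(dtype=float)
    n = len(x)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n_cells, got k={k}, n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    nbr = [set(map(int, row)) for row in idx]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in nbr[i]:
            if graph.has_edge(i, j):
                continue
            inter = len(nbr[i] & nbr[j])
            if inter:
                graph.add_edge(i, j, weight=inter / (2 * k - inter))
    comms = nx.community.louvain_communities(
        graph, weight="weight", seed=seed, resolution=resolution)
    labels = np.empty(n, dtype=int)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    for lab, nodes in enumerate(ordered, start=1):
        labels[list(nodes)] = lab
    return labels


# -------------------------------------------------------------- profiling

@dataclass
class ClusterProfile:
    """Mean normalized expression and fraction-positive per marker of one
    phenocluster — the row block of the heatmap the rules are read from."""

    cluster_id: int
    n_cells: int
    mean_expr: dict
    frac_positive: dict

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("cluster with no cells")
        for m, f in self.frac_positive.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"frac_positive[{m}] = {f} outside [0, 1]")


def profile_clusters(table: pd.DataFrame, labels: np.ndarray,
                     markers: Sequence[str] | None = None,
                     positivity_threshold: float = 0.5,
                     thresholds: Mapping[str, float] | None = None) -> list[ClusterProfile]:
    """Per-cluster column means and positive fractions.

    Positivity is normalized intensity strictly above the threshold
    (default 0.5 normalized units; per-marker overrides via
    ``thresholds``).
    """
    markers = list(markers) if markers is not None else marker_columns(table)
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels do not align with table rows")
    thresholds = dict(thresholds or {})
    profiles = []
    for lab in np.unique(labels):
        sub = table.loc[labels == lab, markers]
        mean_expr = sub.mean().to_dict()
        frac = {m: float((sub[m] > thresholds.get(m, positivity_threshold)).mean())
                for m in markers}
        profiles.append(ClusterProfile(int(lab), len(sub), mean_expr, frac))
    return profiles


# ------------------------------------------------------------ rule engine

class RuleTieError(ValueError):
    """Two matching rules share the same priority; no silent choice."""


@dataclass(frozen=True)
class CellTypeRule:
    type_name: str
    required_positive: tuple[str, ...]
    required_negative: tuple[str, ...]
    priority: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_positive", tuple(self.required_positive))
        object.__setattr__(self, "required_negative", tuple(self.required_negative))
        if self.type_name not in CELL_TYPES:
            raise ValidationError(f"unknown cell type {self.type_name!r}")
        overlap = set(self.required_positive) & set(self.required_negative)
        if overlap:
            raise ValidationError(f"{self.type_name}: markers {overlap} both required and forbidden")


def load_rules(path: str | Path | None = None) -> list[CellTypeRule]:
    """Load a rule table from YAML (default: the packaged nine-type table)."""
    if path is None:
        ref = importlib.resources.files("plexcell.data") / "celltype_rules.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        doc = yaml.safe_load(Path(path).read_text())
    return [
        CellTypeRule(
            type_name=r["type_name"],
            required_positive=tuple(r.get("required_positive", ())),
            required_negative=tuple(r.get("required_negative", ())),
            priority=int(r["priority"]),
        )
        for r in doc["rules"]
    ]


def classify_cluster(profile: ClusterProfile, rules: Sequence[CellTypeRule],
                     min_fraction: float = POSITIVITY_FRACTION) -> str:
    """Highest-priority rule whose positives reach ``min_fraction`` of the
    cluster and whose negatives stay below it; 'Unassigned' if none."""
    fp = profile.frac_positive
    matches = [
        r for r in rules
        if all(fp.get(m, 0.0) >= min_fraction for m in r.required_positive)
        and all(fp.get(m, 0.0) < min_fraction for m in r.required_negative)
    ]
    if not matches:
        return UNASSIGNED
    top = max(r.priority for r in matches)
    winners = [r for r in matches if r.priority == top]
    if len(winners) > 1:
        names = sorted(r.type_name for r in winners)
        raise RuleTieError(f"cluster {profile.cluster_id}: rules {names} tie at priority {top}")
    return winners[0].type_name


def assign_cell_types(table: pd.DataFrame, labels: np.ndarray,
                      rules: Sequence[CellTypeRule] | None = None,
                      markers: Sequence[str] | None = None,
                      positivity_threshold: float = 0.5) -> tuple[pd.DataFrame, list[ClusterProfile], dict]:
    """Cluster-level classification broadcast to cells.

    Returns the table with ``cluster_id`` and ``cell_type`` columns, the
    cluster profiles, and the ``cluster_id -> type`` map.
    """
    rules = rules if rules is not None else load_rules()
    profiles = profile_clusters(table, labels, markers,
                                positivity_threshold=positivity_threshold)
    mapping = {p.cluster_id: classify_cluster(p, rules) for p in profiles}
    out = table.copy()
    out["cluster_id"] = np.asarray(labels)
    out["cell_type"] = out["cluster_id"].map(mapping)
    return out, profiles, mapping


# ----------------------------------------------------- T-cell state caller

@dataclass
class CaseTCellState:
    case_id: str
    state: str
    lymphocyte_density_per_mm2: float
    pd1_frac: float
    tcf7_frac: float

    def __post_init__(self) -> None:
        if self.state not in TCELL_STATES:
            raise ValidationError(f"state {self.state!r} not in {TCELL_STATES}")


def classify_tcell_state(table: pd.DataFrame, area_mm2: float,
                         density_min: float = 60.0,
                         theta_hi: float = 0.33, theta_lo: float = 0.33,
                         positivity_threshold: float = 0.5,
                         pd1_marker: str = "PD1",
                         tcf7_marker: str = "TCF7") -> CaseTCellState:
    """Call the case's predominant T-cell phenotype.

    Below ``density_min`` lymphocytes (CD4_T + CD8_T + NK) per mm² the
    case is Deserted. Otherwise PD1 and TCF7 positive fractions among
    CD8 T cells decide: PD1-high / TCF7-low is acute exhaustion,
    TCF7-present / PD1-low is chronic exhaustion, both high is mixed.
    Both low — no exhaustion phenotype despite the infiltrate — is
    called Deserted (passer-by), making the rule a total partition.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    if "cell_type" not in table.columns:
        raise ValueError("cell types must be assigned before state calling")
    case_id = str(table["case_id"].iloc[0]) if len(table) else "case"
    lymph = table[table["cell_type"].isin(LYMPHOID_TYPES)]
    dens = len(lymph) / area_mm2
    cd8 = table[table["cell_type"] == "CD8_T"]
    if len(cd8):
        pd1_frac = float((cd8[pd1_marker] > positivity_threshold).mean())
        tcf7_frac = float((cd8[tcf7_marker] > positivity_threshold).mean())
    else:
        pd1_frac = tcf7_frac = 0.0
    if dens < density_min:
        state = "Deserted"
    elif len(cd8) == 0:
        warnings.warn(f"case {case_id}: lymphocyte density {dens:.0f}/mm2 but no CD8 T cells")
        state = "Deserted"
    elif pd1_frac >= theta_hi and tcf7_frac >= theta_lo:
        state = "T_ex-mixed"
    elif pd1_frac >= theta_hi:
        state = "T_ex-acute"
    elif tcf7_frac >= theta_lo:
        state = "T_ex-chronic"
    else:
        state = "Deserted"
    return CaseTCellState(case_id, state, dens, pd1_frac, tcf7_frac)


# ------------------------------------------------------------ composition

def composition(table: pd.DataFrame) -> dict:
    """Percentage of each assigned cell type among all typed inflammatory
    cells (Unassigned excluded); sums to 100 when non-empty."""
    if "cell_type" not in table.columns:
        raise ValueError("cell types must be assigned before composition")
    typed = table[table["cell_type"].isin(CELL_TYPES)]
    if not len(typed):
        return {}
    counts = typed["cell_type"].value_counts()
    return {t: 100.0 * c / len(typed) for t, c in counts.items()}
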