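"""1-D topographic network construction.

Each population (PY, IN, TC, RE) is a 1-D layer.  A projection connects every
source cell to the target cells within a fixed radius of its mapped centre in
the target layer; layers of different size are aligned proportionally
(endpoints to endpoints).  Wiring is fully deterministic given the spec.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .synapses import SynapseParams

__all__ = ["ProjectionSpec", "NetworkSpec", "Network", "map_center",
           "build_connectivity", "assemble"]

# (source, target) -> (synapse types, modulator tag, depressing?, mini key,
# conductance normalization).  Intracortical conductances are per-connection
# values (matching the per-connection miniature-PSP quanta); projections that
# involve the thalamus are per-target totals shared across the realized
# fan-in.
_DEFAULT_PROJ = [
    ("PY", "PY", ("AMPA", "NMDA"), "lach", True, "PY_PY", "per_connection"),
    ("PY", "IN", ("AMPA", "NMDA"), None, True, "PY_IN", "per_connection"),
    ("IN", "PY", ("GABAA",), "lgaba", False, "IN_PY", "per_connection"),
    ("TC", "PY", ("AMPA",), "lach", False, None, "total"),
    ("TC", "IN", ("AMPA",), "lach", False, None, "total"),
    ("PY", "TC", ("AMPA",), None, False, None, "total"),
    ("PY", "RE", ("AMPA",), None, False, None, "total"),
    ("TC", "RE", ("AMPA",), None, False, None, "total"),
    ("RE", "TC", ("GABAA", "GABAB"), "lgaba", False, None, "total"),
    ("RE", "RE", ("GABAA",), "lgaba", False, None, "total"),
]


@dataclass
class ProjectionSpec:
    source: str
    target: str
    syn_types: tuple[str, ...]
    radius: int
    g_syn: dict[str, float]            # uS per synapse type (per-target total)
    modulator: str | None = None       # "lach" | "lgaba" | None
    depressing: bool = False
    mini_key: str | None = None        # key into constants.G_MINI
    normalization: str | None = None   # per_connection | total | None=spec

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        for t in self.syn_types:
            if t not in ("AMPA", "NMDA", "GABAA", "GABAB"):
                raise ValueError(f"unknown synapse type {t!r}")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class NetworkSpec:
    """Population sizes, projections and wiring rules."""
    sizes: dict[str, int] = field(default_factory=lambda: {
        "PY": C.N_PY, "IN": C.N_IN, "TC": C.N_TC, "RE": C.N_RE})
    projections: list[ProjectionSpec] = field(default_factory=list)
    boundary: str = "truncate"         # "truncate" | "periodic"
    normalization: str = "per_connection"  # per_connection | total
    seed: int = 0

    def __post_init__(self):
        for pop, n in self.sizes.items():
            if n < 1:
                raise ValueError(f"population {pop} must have >= 1 cell")
        if self.boundary not in ("truncate", "periodic"):
            raise ValueError("boundary must be 'truncate' or 'periodic'")
        if not self.projections:
            self.projections = default_projections()
        for p in self.projections:
            if p.source not in self.sizes or p.target not in self.sizes:
                raise ValueError(f"projection {p.name} references an unknown "
                                 "population")

    @classmethod
    def default(cls, **kw) -> "NetworkSpec":
        return cls(**kw)

    @classmethod
    def reduced(cls, factor: int = 5, **kw) -> "NetworkSpec":
        """Desk-scale surrogate: populations divided by ``factor``.

        Intracortical radii are kept at their full-scale values so that each
        cortical cell keeps the same fan-in (and hence the same miniature-PSP
        statistics) as in the full network; radii of thalamic projections are
        divided by ``factor`` (rounded up, minimum 1)."""
        sizes = {p: max(n // factor, 1)
                 for p, n in {"PY": C.N_PY, "IN": C.N_IN,
                              "TC": C.N_TC, "RE": C.N_RE}.items()}
        cortical = {("PY", "PY"), ("PY", "IN"), ("IN", "PY")}
        projections = default_projections(
            radius_map={k: (r if k in cortical
                            else max(math.ceil(r / factor), 1))
                        for k, r in C.RADII.items()})
        return cls(sizes=sizes, projections=projections, **kw)


def default_projections(radius_map=None) -> list[ProjectionSpec]:
    radius_map = radius_map or C.RADII
    out = []
    for src, tgt, types, mod, dep, mini, norm in _DEFAULT_PROJ:
        g = {t: C.G_SYN[(src, tgt, t)] for t in types}
        out.append(ProjectionSpec(src, tgt, types, radius_map[(src, tgt)], g,
                                  modulator=mod, depressing=dep,
                                  mini_key=mini, normalization=norm))
    return out


def map_center(source_index: int, source_size: int, target_size: int) -> int:
    """Proportional cross-layer index mapping; endpoints map to endpoints.

    Rounding rule: nearest integer of i*(target_size-1)/(source_size-1)
    (half away from zero); a singleton source layer maps to the target centre.
    """
    if source_size < 1 or target_size < 1:
        raise ValueError("layers must be non-empty")
    if not 0 <= source_index < source_size:
        raise ValueError("source_index out of range")
    if source_size == 1:
        return (target_size - 1) // 2
    return int(math.floor(source_index * (target_size - 1)
                          / (source_size - 1) + 0.5))


@dataclass
class Edges:
    """Edge list of one projection in target-sorted (CSR) order."""
    src: np.ndarray          # presynaptic index per edge
    dst: np.ndarray          # postsynaptic index per edge
    indptr: np.ndarray       # CSR row pointer over target cells
    fan_in: np.ndarray       # realised fan-in per target cell

    def __len__(self):
        return len(self.src)


def _project_edges(n_src, n_tgt, radius, same_pop, boundary):
    """Receiver-centric wiring: target j receives from every source within
    ``radius`` (source-layer index units) of its mapped centre.  Interior
    fan-in is 2r+1 across populations and 2r within a population (no
    self-edges); boundary cells have truncated fan-in under the default
    rule."""
    src_list, dst_list = [], []
    r = radius
    if r >= n_src:
        warnings.warn("radius >= source layer size; using full connectivity")
    for j in range(n_tgt):
        c = map_center(j, n_tgt, n_src)
        for i in range(c - r, c + r + 1):
            if boundary == "periodic":
                i = i % n_src
            elif not 0 <= i < n_src:
                continue
            if same_pop and j == i:
                continue
            src_list.append(i)
            dst_list.append(j)
    src = np.asarray(src_list, dtype=np.int64)
    dst = np.asarray(dst_list, dtype=np.int64)
    order = np.lexsort((src, dst))
    src, dst = src[order], dst[order]
    fan_in = np.bincount(dst, minlength=n_tgt).astype(np.int64)
    indptr = np.concatenate(([0], np.cumsum(fan_in)))
    return Edges(src=src, dst=dst, indptr=indptr, fan_in=fan_in)


def build_connectivity(spec: NetworkSpec) -> dict[str, Edges]:
    """Deterministic edge lists for every projection in the spec."""
    out = {}
    for p in spec.projections:
        out[p.name] = _project_edges(
            spec.sizes[p.source], spec.sizes[p.target], p.radius,
            p.source == p.target, spec.boundary)
    return out


@dataclass
class Network:
    """Assembled, runnable network: spec, wiring and per-projection synapses."""
    spec: NetworkSpec
    edges: dict[str, Edges]
    synapse_params: dict[tuple[str, str, str], SynapseParams]
    projections: dict[str, ProjectionSpec]

    @property
    def sizes(self):
        return self.spec.sizes

    def summary(self) -> pd.DataFrame:
        """Per-projection edge counts as a columnar table."""
        rows = []
        for name, p in self.projections.items():
            e = self.edges[name]
            rows.append(dict(projection=name, radius=p.radius,
                             synapse_types="+".join(p.syn_types),
                             n_edges=len(e),
                             mean_fan_in=float(e.fan_in.mean())))
        return pd.DataFrame(rows)


def assemble(spec: NetworkSpec, cell_params=None,
             synapse_overrides: dict | None = None) -> Network:
    """Bind every projection to synapse parameters and freeze the wiring.

    ``synapse_overrides`` maps (source, target, type) to a SynapseParams that
    replaces the table default (used by the propofol decay-time scaling).
    """
    edges = build_connectivity(spec)
    syn = {}
    for p in spec.projections:
        for t in p.syn_types:
            key = (p.source, p.target, t)
            if synapse_overrides and key in synapse_overrides:
                syn[key] = synapse_overrides[key]
            else:
                syn[key] = SynapseParams(
                    type=t, g_syn=p.g_syn[t],
                    depression_u=C.DEPRESSION_U if p.depressing else 0.0)
    return Network(spec=spec, edges=edges, synapse_params=syn,
                   projections={p.name: p for p in spec.projections})
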