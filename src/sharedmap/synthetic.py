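"""Synthetic registry data with the structure the joint model assumes.

The generator emulates a two-disease mortality registry on 47 areas,
2 genders and 5 age groups: an abundant disease (~1e5 deaths) and a sparse
one (~1e4 deaths) sharing a spatially correlated log-rate surface per
gender, with a disease-2-specific unstructured deviation and strong
age/gender skew in the populations at risk.  All randomness flows through
an explicit seed; there is no hidden global RNG state.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .graph import AreaGraph, StructureMatrix, icar_structure, load_spain_fixture
from .model import (
    CountData,
    DEFAULT_AGE_LABELS,
    ModelSpec,
    ParameterState,
    apply_constraints,
    linear_predictor_field,
)

# Default generating values: shared-surface scaling and component precisions
# put the crude-rate magnitudes in the registry's decade without claiming to
# match it (delta, tau_kappa, tau_u, tau_eta, and per-disease base rates).
DEFAULT_TRUTH = {
    "delta": 1.2,
    "tau_kappa": 2.0,
    "tau_u": 4.0,
    "tau_eta": 1.0,
    "alpha1": float(np.log(5e-4)),
    "alpha2": float(np.log(5e-5)),
}

# Person-years at risk per average area, gender and age group over a 5-year
# window (ages 30-44, 45-59, 60-74, 75-89, 90+), in the magnitude of a
# mid-size European province.
_BASE_PERSON_YEARS = np.array([585e3, 500e3, 350e3, 175e3, 25e3])
_AREA_SIZE_LOG_SD = 1.0  # right-skewed area sizes: few large, many small


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    theta: ParameterState
    spec: ModelSpec
    graph: AreaGraph
    n: np.ndarray
    seed: int


def make_graph(kind: str, *, m: int = 3, I: int = 20, p: float = 0.2,
               seed: int | None = None) -> AreaGraph:
    """Build a study topology: ``"grid"`` (m x m rook lattice),
    ``"spain"`` (packaged 47-province fixture) or ``"random"``
    (Erdos-Renyi G(I, p), resampled until connected)."""
    if kind == "grid":
        g = nx.grid_2d_graph(m, m)
        nodes = sorted(g.nodes())
        pos = {node: k for k, node in enumerate(nodes)}
        ids = tuple(f"a{r}_{c}" for r, c in nodes)
        edges = frozenset((min(pos[a], pos[b]), max(pos[a], pos[b])) for a, b in g.edges())
        return AreaGraph(ids, edges)
    if kind == "spain":
        return load_spain_fixture()
    if kind == "random":
        if seed is None:
            raise ValueError("random graphs require a seed")
        rng = np.random.default_rng(seed)
        for _ in range(1000):
            g = nx.gnp_random_graph(I, p, seed=int(rng.integers(2 ** 31)))
            if nx.is_connected(g):
                ids = tuple(f"a{k}" for k in range(I))
                edges = frozenset((min(a, b), max(a, b)) for a, b in g.edges())
                return AreaGraph(ids, edges)
        raise RuntimeError(f"no connected G({I}, {p}) found in 1000 attempts")
    raise ValueError(f"unknown graph kind {kind!r}")


def sample_icar(graph: AreaGraph | StructureMatrix, tau_kappa: float,
                seed: int | np.random.Generator) -> np.ndarray:
    """One draw from the sum-to-zero-constrained ICAR distribution.

    Uses the eigendecomposition of ``R`` restricted to its non-null space:
    independent ``N(0, (tau * lam_k)**-1)`` coordinates mapped back through
    the orthonormal eigenvectors, so every draw sums to zero exactly within
    each connected component.
    """
    if tau_kappa <= 0:
        raise ValueError("tau_kappa must be positive")
    struct = graph if isinstance(graph, StructureMatrix) else icar_structure(graph)
    A, lam = struct.eigenbasis()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(lam.size) / np.sqrt(tau_kappa * lam)
    return A @ z


def make_populations(I: int, paper_scale: bool = True,
                     seed: int | np.random.Generator = 0,
                     J: int = 5) -> np.ndarray:
    """Populations at risk (person-years), identical for both diseases.

    Age profile falls steeply for the oldest groups and area sizes are
    log-normal with log-sd 1 (mean-one multipliers), so at the default
    generating values the sparse disease has small per-cell expected counts
    (median below 10) while the abundant disease is roughly an order of
    magnitude larger.  ``paper_scale=False`` divides everything by 50 for
    fast tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = _BASE_PERSON_YEARS[:J].copy()
    if not paper_scale:
        base = base / 50.0
    sd = _AREA_SIZE_LOG_SD
    mult = np.exp(rng.normal(-0.5 * sd ** 2, sd, size=I))  # mean 1, median < 1
    n_area = mult[:, None, None] * base[None, None, :]  # (I, 1, J)
    n = np.broadcast_to(n_area, (I, 2, J)).copy()  # same for both genders
    return np.broadcast_to(n[None], (2, I, 2, J)).copy()


def default_truth(graph: AreaGraph, seed: int,
                  spec: ModelSpec | None = None,
                  paper_scale: bool = True,
                  **overrides: float) -> SyntheticTruth:
    """Draw a ground-truth parameter state from the model's own priors.

    ``kappa`` columns are ICAR draws at ``tau_kappa``, ``u`` is iid normal
    at ``tau_u`` and ``eta`` iid normal at ``tau_eta`` centred to sum to
    zero, matching the identifiability constraints the fitter imposes.
    Keyword overrides replace any entry of the default generating values.
    """
    spec = spec or ModelSpec.selected()
    vals = {**DEFAULT_TRUTH, **overrides}
    rng = np.random.default_rng(seed)
    I, J = graph.n_areas, len(DEFAULT_AGE_LABELS)
    struct = icar_structure(graph)

    kappa = None
    if spec.has_spatial:
        kappa = np.column_stack([
            sample_icar(struct, vals["tau_kappa"], rng)
            for _ in range(spec.n_kappa_cols)
        ])
    u = None
    if spec.u_diseases:
        u = rng.normal(0.0, vals["tau_u"] ** -0.5, size=(len(spec.u_diseases), I))
    eta = None
    if spec.n_eta_rows:
        eta = rng.normal(0.0, vals["tau_eta"] ** -0.5, size=(spec.n_eta_rows, J))

    theta = ParameterState(
        alpha=np.array([vals["alpha1"], vals["alpha2"]]),
        log_delta=float(np.log(vals["delta"])),
        kappa=kappa, u=u, eta=eta,
        tau_kappa=vals["tau_kappa"], tau_u=vals["tau_u"], tau_eta=vals["tau_eta"],
    )
    theta = apply_constraints(theta, spec, struct.component_labels)
    n = make_populations(I, paper_scale=paper_scale, seed=rng, J=J)
    return SyntheticTruth(theta=theta, spec=spec, graph=graph, n=n, seed=seed)


def simulate_counts(truth: SyntheticTruth, spec: ModelSpec | None = None,
                    seed: int | np.random.Generator | None = None) -> CountData:
    """Poisson counts ``O ~ Poisson(n * r)`` at the truth's rates."""
    spec = spec or truth.spec
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(truth.seed + 1 if seed is None else seed))
    I, J = truth.n.shape[1], truth.n.shape[3]
    lp = linear_predictor_field(spec, truth.theta, I, J)
    mu = truth.n * np.exp(lp)
    O = rng.poisson(mu)
    age = DEFAULT_AGE_LABELS[:J]
    return CountData(O=O, n=truth.n, area_ids=truth.graph.area_ids, age_labels=age)


def simulate_dataset(seed: int, graph: AreaGraph | None = None,
                     spec: ModelSpec | None = None, paper_scale: bool = True,
                     **overrides: float) -> tuple[CountData, SyntheticTruth]:
    """Convenience wrapper: truth + counts on a given topology (default Spain)."""
    graph = graph or make_graph("spain")
    truth = default_truth(graph, seed, spec=spec, paper_scale=paper_scale, **overrides)
    data = simulate_counts(truth)
    return data, truth
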