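"""Synthetic stem-to-tissue differentiation data with known ground truth.

The generator emulates the structure the pipeline is built to recover: a
*stemness* gene module whose expression decays with differentiation,
several *tissue* modules that rise in their own lineage, and a large
*invariant* bulk. Every cell carries a latent time t in [0, 1] and a
lineage; stem-module genes follow the activation weight (1 - t)^2 in all
cells, tissue-module genes follow t^2 in cells of their lineage, and
counts are drawn from a negative binomial around the resulting means
(gamma-Poisson mixture with shape ``noise_dispersion``; infinite shape
gives the Poisson limit). Spliced and unspliced abundances follow the
closed-form solution of first-order splicing kinetics
``du/dt = alpha(t) - beta u``, ``ds/dt = beta u - gamma s``, with the
transcription rate alpha switching on at t = 0 for rising modules and off
for the decaying stem module, so the true velocity sign of every
gene-cell pair is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .som import Portrait, SOMGrid

DEFAULT_N_CELLS = 800
DEFAULT_N_GENES = 2000
DEFAULT_N_LINEAGES = 2
DEFAULT_FRAC_INVARIANT = 0.65  # the dominant share of genes never changes
DEFAULT_DISPERSION = 0.5

# fraction of latent time below which a cell is "stem", above 2/3 "tissue"
_STEM_T = 1.0 / 3.0
_TISSUE_T = 2.0 / 3.0

_KINETIC_TIME_SCALE = 4.0  # latent-time unit in kinetic time units


@dataclass
class SyntheticTruth:
    """Ground truth of one generated snapshot."""

    latent_time: pd.Series  # cell -> t in [0, 1]
    lineage: pd.Series  # cell -> tissue_i
    gene_module: pd.Series  # gene -> stem / tissue_i / invariant
    kinetics: pd.DataFrame  # gene -> alpha_on, alpha_off, beta, gamma_true
    amplitude: pd.Series  # gene -> activation amplitude a_g
    seed: int


@dataclass
class SyntheticData:
    counts: ExpressionMatrix
    spliced: ExpressionMatrix
    unspliced: ExpressionMatrix
    annotations: pd.DataFrame  # cell_id, cell_type, lineage
    truth: SyntheticTruth


def _kinetic_solution(alpha, beta, gamma, u0, s0, tau):
    """u(tau), s(tau) for constant alpha from initial condition (u0, s0)."""
    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    u = u0 * eb + (alpha / beta) * (1.0 - eb)
    D = (beta * u0 - alpha) / (gamma - beta)
    C = s0 - alpha / gamma - D
    s = alpha / gamma + C * eg + D * eb
    return u, s


def generate_differentiation(
    n_cells: int = DEFAULT_N_CELLS,
    n_genes: int = DEFAULT_N_GENES,
    n_lineages: int = DEFAULT_N_LINEAGES,
    frac_invariant: float = DEFAULT_FRAC_INVARIANT,
    noise_dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    activation_exponent: float = 2.0,
    steady_state: bool = False,
) -> SyntheticData:
    """Simulate a differentiation snapshot with known ground truth.

    ``noise_dispersion`` is the negative-binomial shape: the count
    variance is ``mu + mu^2 / dispersion`` (``np.inf`` gives Poisson).
    With ``steady_state=True`` the spliced/unspliced abundances are the
    exact steady states of each cell's current transcription rate, so
    ``u = (gamma/beta) s`` holds identically — useful for validating the
    ratio fit.
    """
    if n_lineages < 1:
        raise ValueError("need at least one lineage")
    if not 0.0 <= frac_invariant < 1.0:
        raise ValueError("frac_invariant must lie in [0, 1)")
    if noise_dispersion <= 0:
        raise ValueError("noise_dispersion must be positive (np.inf for Poisson)")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cell_ids = [f"c{i:05d}" for i in range(n_cells)]

    # --- gene modules ----------------------------------------------------
    n_var = n_genes - int(round(frac_invariant * n_genes))
    per_module = n_var // (n_lineages + 1)
    if per_module < 1:
        raise ValueError("too few variant genes for the requested lineages")
    modules = np.array(["invariant"] * n_genes, dtype=object)
    modules[:per_module] = "stem"
    for li in range(n_lineages):
        lo = per_module * (li + 1)
        modules[lo : lo + per_module] = f"tissue_{li + 1}"
    perm = rng.permutation(n_genes)  # decouple module from gene order
    modules = modules[perm]

    baseline = rng.lognormal(mean=np.log(3.0), sigma=0.8, size=n_genes)
    amplitude = rng.uniform(2.0, 5.0, size=n_genes)
    amplitude[modules == "invariant"] = 0.0

    # --- cells -----------------------------------------------------------
    lineage_idx = rng.integers(1, n_lineages + 1, size=n_cells)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    lineage = np.array([f"tissue_{i}" for i in lineage_idx], dtype=object)
    cell_type = np.where(
        t < _STEM_T,
        "stem",
        np.where(
            t < _TISSUE_T,
            np.char.add("progenitor_", lineage_idx.astype(str)),
            np.char.add("tissue_", lineage_idx.astype(str)),
        ),
    ).astype(object)

    # --- activation weights and count means ------------------------------
    w = np.zeros((n_genes, n_cells))
    stem_rows = modules == "stem"
    w[stem_rows, :] = (1.0 - t[None, :]) ** activation_exponent
    for li in range(1, n_lineages + 1):
        rows = modules == f"tissue_{li}"
        cols = lineage_idx == li
        w[np.ix_(rows, cols)] = (t[cols][None, :]) ** activation_exponent
    mu = baseline[:, None] * (1.0 + amplitude[:, None] * w)

    if np.isinf(noise_dispersion):
        counts = rng.poisson(mu).astype(float)
    else:
        lam = rng.gamma(shape=noise_dispersion, scale=mu / noise_dispersion)
        counts = rng.poisson(lam).astype(float)

    # --- splicing kinetics ------------------------------------------------
    beta = np.ones(n_genes)
    gamma = rng.uniform(0.3, 0.8, size=n_genes)
    alpha_off = gamma * baseline  # off steady state has s = baseline
    alpha_on = gamma * baseline * (1.0 + amplitude)
    tau = _KINETIC_TIME_SCALE * t

    a = np.broadcast_to(alpha_off[:, None], (n_genes, n_cells)).copy()
    u0 = np.broadcast_to((alpha_off / beta)[:, None], (n_genes, n_cells)).copy()
    s0 = np.broadcast_to(baseline[:, None], (n_genes, n_cells)).copy()
    # rising tissue genes: alpha switches on at t = 0 in their own lineage
    for li in range(1, n_lineages + 1):
        rows = modules == f"tissue_{li}"
        cols = lineage_idx == li
        a[np.ix_(rows, cols)] = np.broadcast_to(
            alpha_on[rows][:, None], (rows.sum(), cols.sum())
        )
    # stem genes: start at the on steady state, alpha switches off at t = 0
    a[stem_rows, :] = alpha_off[stem_rows][:, None]
    u0[stem_rows, :] = (alpha_on / beta)[stem_rows][:, None]
    s0[stem_rows, :] = (alpha_on / gamma)[stem_rows][:, None]

    if steady_state:
        # quasi-static limit: abundances track the current rate
        a_now = baseline[:, None] * gamma[:, None] * (1.0 + amplitude[:, None] * w)
        u = a_now / beta[:, None]
        s = a_now / gamma[:, None]
    else:
        u, s = _kinetic_solution(
            a, beta[:, None], gamma[:, None], u0, s0, tau[None, :]
        )

    annotations = pd.DataFrame(
        {"cell_id": cell_ids, "cell_type": cell_type, "lineage": lineage}
    )
    truth = SyntheticTruth(
        latent_time=pd.Series(t, index=cell_ids, name="latent_time"),
        lineage=pd.Series(lineage, index=cell_ids, name="lineage"),
        gene_module=pd.Series(modules, index=gene_ids, name="gene_module"),
        kinetics=pd.DataFrame(
            {
                "alpha_on": alpha_on,
                "alpha_off": alpha_off,
                "beta": beta,
                "gamma_true": gamma,
            },
            index=gene_ids,
        ),
        amplitude=pd.Series(amplitude, index=gene_ids, name="amplitude"),
        seed=seed,
    )
    return SyntheticData(
        counts=ExpressionMatrix(counts, gene_ids, cell_ids, "raw"),
        spliced=ExpressionMatrix(s, gene_ids, cell_ids, "spliced"),
        unspliced=ExpressionMatrix(u, gene_ids, cell_ids, "unspliced"),
        annotations=annotations,
        truth=truth,
    )


def true_velocity(data: SyntheticData) -> np.ndarray:
    """Ground-truth ds/dt = beta * u - gamma * s per gene and cell."""
    beta = data.truth.kinetics["beta"].to_numpy()[:, None]
    gamma = data.truth.kinetics["gamma_true"].to_numpy()[:, None]
    return beta * data.unspliced.values - gamma * data.spliced.values


# ---------------------------------------------------------------------------
# toy graph and grid fixtures for the trajectory oracles
# ---------------------------------------------------------------------------


def generate_toy_graph(kind: str, params: dict | None = None, seed: int = 0):
    """Small deterministic fixtures for path-finding tests.

    ``chain``: params n (nodes), caps (n-1 capacities) -> path graph
    S, X1, ..., T.  ``diamond``: params caps = [S-A, A-T, S-B, B-T] ->
    two parallel two-edge routes.  ``grid``: params rows, cols, valley
    (list of (row, col)) -> a Portrait of elevation 1 with zeros along
    the valley.  ``random``: params n, p (edge prob), connected simple
    graph with uniform capacities in (0, 1].
    """
    params = dict(params or {})
    if kind == "chain":
        caps = list(params.get("caps", [5.0, 3.0]))
        n = params.get("n", len(caps) + 1)
        if len(caps) != n - 1:
            raise ValueError("chain needs n-1 capacities")
        names = ["S"] + [f"X{i}" for i in range(1, n - 1)] + ["T"]
        g = nx.Graph()
        for i, c in enumerate(caps):
            g.add_edge(names[i], names[i + 1], capacity=float(c))
        return g
    if kind == "diamond":
        caps = list(params.get("caps", [2.0, 5.0, 4.0, 3.0]))
        if len(caps) != 4:
            raise ValueError("diamond needs 4 capacities")
        g = nx.Graph()
        g.add_edge("S", "A", capacity=float(caps[0]))
        g.add_edge("A", "T", capacity=float(caps[1]))
        g.add_edge("S", "B", capacity=float(caps[2]))
        g.add_edge("B", "T", capacity=float(caps[3]))
        return g
    if kind == "grid":
        rows = int(params.get("rows", 5))
        cols = int(params.get("cols", 5))
        valley = params.get("valley")
        grid = SOMGrid(rows, cols)
        height = np.ones(grid.n_nodes)
        if valley is None:
            valley = [(r, cols // 2) for r in range(rows)]
        for r, c in valley:
            height[grid.node_index(r, c)] = 0.0
        return Portrait(grid=grid, values=height, subject="toy-valley", scale_tag="logfc")
    if kind == "random":
        rng = np.random.default_rng(seed)
        n = int(params.get("n", 8))
        p = float(params.get("p", 0.4))
        while True:
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            if n < 2 or nx.is_connected(g):
                break
        out = nx.Graph()
        out.add_nodes_from(f"n{i}" for i in range(n))
        for uu, vv in g.edges:
            out.add_edge(f"n{uu}", f"n{vv}", capacity=float(rng.uniform(0.05, 1.0)))
        return out
    raise ValueError(f"unknown toy fixture kind {kind!r}")
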