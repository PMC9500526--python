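"""Serial-sampling haploid coalescent simulator for two demographic models.

The simulator generates genealogies of heterochronously sampled mtDNA
lineages from two groups — an older group A (e.g. Bronze Age
individuals) and a younger group B (e.g. Iron Age individuals) — under
one of two topologies:

``continuity``
    a single constant-size deme of haploid effective size ``N_anc``
    holds both sample groups serially: group B descends directly from
    the population that produced group A.

``discontinuity``
    group B lineages coalesce within their own deme of size ``N_sic``
    back to a divergence time ``T_div`` (years BP, older than every
    sample), at which point the surviving lineages merge into the
    ``N_anc`` deme shared with group A: group B derives from a
    population that split from the ancestors of group A.

Time runs backwards in generations before present; sampled lineages
activate when the simulation clock passes their age.  ``N`` follows
the mtDNA convention of counting transmitting lineages, so ``k``
active lineages coalesce at rate ``k(k-1)/2 / N`` per generation.
Mutations are dropped on branches as a Poisson process (finite sites,
Jukes-Cantor: uniform site, uniform different base) at rate
``mu * gen_time * L`` per branch generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .diversity import _DECODE
from .seq_io import Alignment, GroupedAlignment

DEFAULT_LOCUS_LENGTH = 16_569   # rCRS mtDNA frame
DEFAULT_GEN_TIME = 25.0         # years per generation


@dataclass(frozen=True)
class DemographicModel:
    """Topology and parameters of one demographic hypothesis.

    Sizes are haploid effective sizes (transmitting mtDNA lineages);
    ``t_div`` is in years BP; ``mu`` is the mutation rate per site per
    year.
    """

    topology: str                       # "continuity" | "discontinuity"
    n_anc: float
    mu: float
    n_sic: float | None = None
    t_div: float | None = None
    L: int = DEFAULT_LOCUS_LENGTH
    gen_time: float = DEFAULT_GEN_TIME

    def __post_init__(self) -> None:
        if self.topology not in {"continuity", "discontinuity"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_anc <= 0 or self.mu <= 0 or self.L <= 0 or self.gen_time <= 0:
            raise ValueError("sizes, rates and lengths must be positive")
        if self.topology == "discontinuity":
            if self.n_sic is None or self.t_div is None:
                raise ValueError("discontinuity requires n_sic and t_div")
            if self.n_sic <= 0:
                raise ValueError("n_sic must be positive")


@dataclass(frozen=True)
class SamplingConfig:
    """Two serially sampled groups: sizes, ages (years BP) and labels."""

    n_a: int = 8
    age_a: float = 3500.0
    n_b: int = 17
    age_b: float = 2450.0
    label_a: str = "bronze_age"
    label_b: str = "sicanian"

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.age_a < 0 or self.age_b < 0:
            raise ValueError("ages must be non-negative")
        if self.age_a <= self.age_b:
            raise ValueError("group A must be older than group B")

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    def validate_against(self, model: DemographicModel) -> None:
        if model.topology == "discontinuity" and model.t_div <= self.age_a:
            raise ValueError("t_div must predate the oldest sample")


@dataclass(frozen=True)
class Prior:
    """A uniform or log-uniform prior over one scalar parameter."""

    dist: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in {"uniform", "loguniform"}:
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if not (self.low < self.high):
            raise ValueError("prior low must be < high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform support must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass(frozen=True)
class PriorSet:
    """Named independent priors over the parameters of one topology."""

    topology: str
    priors: dict[str, Prior]

    REQUIRED = {
        "continuity": ("n_anc", "mu"),
        "discontinuity": ("n_anc", "mu", "n_sic", "t_div"),
    }

    def __post_init__(self) -> None:
        missing = [p for p in self.REQUIRED[self.topology] if p not in self.priors]
        if missing:
            raise ValueError(f"priors missing for parameters: {missing}")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {name: p.draw(rng) for name, p in self.priors.items()}

    def contains(self, params: dict[str, float]) -> bool:
        return all(
            self.priors[k].contains(v) for k, v in params.items()
            if k in self.priors
        )


def default_priors(topology: str) -> PriorSet:
    """Package-default priors for either topology.

    Effective sizes log-uniform on [500, 5000] lineages, mutation rate
    log-uniform on [1e-8, 5e-8] per site per year (the conventional
    whole-mtDNA range), and for discontinuity a Neolithic divergence
    window Uniform(6000, 8000) years BP.
    """
    base = {
        "n_anc": Prior("loguniform", 500.0, 5000.0),
        "mu": Prior("loguniform", 1e-8, 5e-8),
    }
    if topology == "discontinuity":
        base["n_sic"] = Prior("loguniform", 500.0, 5000.0)
        base["t_div"] = Prior("uniform", 6000.0, 8000.0)
    return PriorSet(topology=topology, priors=base)


@dataclass(frozen=True)
class Genealogy:
    """Binary genealogy over heterochronous samples.

    ``parent[i]`` indexes the parent of node ``i`` (-1 at the root);
    ``time[i]`` is in generations before present.  Leaves are nodes
    ``0..n_leaves-1`` in sampling order, labelled by group.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n_nodes = 2 * self.n_leaves - 1
        if self.parent.shape != (n_nodes,) or self.time.shape != (n_nodes,):
            raise ValueError("genealogy arrays have wrong shape")
        lengths = self.branch_lengths()
        if (lengths[:-1] < -1e-9).any():
            raise ValueError("negative branch length")

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        out = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(2 * self.n_leaves - 1)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                out[par].append(node)
        return out


# ---------------------------------------------------------------------------
# genealogy simulation


def simulate_genealogy(
    model: DemographicModel,
    sampling: SamplingConfig,
    rng: np.random.Generator | int | None = None,
) -> Genealogy:
    """Simulate one genealogy under the model's topology.

    Standard backwards-in-time coalescent with serial sampling: between
    structural events (sample activation, deme merger) waiting times to
    the next coalescence in each deme are exponential with rate
    ``k(k-1)/2 / N``; exponential memorylessness lets candidate times
    be redrawn after every structural event.
    """
    rng = np.random.default_rng(rng)
    sampling.validate_against(model)
    gt = model.gen_time

    leaf_labels = (sampling.label_a,) * sampling.n_a + (
        sampling.label_b,
    ) * sampling.n_b
    n = sampling.n_total
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)

    two_demes = model.topology == "discontinuity"
    t_div_gen = model.t_div / gt if two_demes else math.inf
    deme_size = [model.n_anc, model.n_sic if two_demes else 0.0]

    # (activation time in generations, leaf id, deme)
    pending: list[tuple[float, int, int]] = []
    for i in range(sampling.n_a):
        pending.append((sampling.age_a / gt, i, 0))
    deme_b = 1 if two_demes else 0
    for i in range(sampling.n_b):
        pending.append((sampling.age_b / gt, sampling.n_a + i, deme_b))
    pending.sort(key=lambda e: e[0])
    for t_act, leaf, _ in pending:
        time[leaf] = t_act

    active: list[list[int]] = [[], []]
    merged = not two_demes
    t = 0.0
    next_node = n
    pend_iter = 0

    while True:
        n_active = len(active[0]) + len(active[1])
        if pend_iter >= len(pending) and n_active <= 1:
            break
        t_act = pending[pend_iter][0] if pend_iter < len(pending) else math.inf
        # candidate coalescence per deme at current sizes
        t_coal = math.inf
        coal_deme = -1
        for deme in (0, 1):
            k = len(active[deme])
            if k >= 2:
                rate = k * (k - 1) / 2.0 / deme_size[deme]
                cand = t + rng.exponential(1.0 / rate)
                if cand < t_coal:
                    t_coal = cand
                    coal_deme = deme
        t_merge = t_div_gen if not merged else math.inf

        t_next = min(t_act, t_coal, t_merge)
        if math.isinf(t_next):
            raise RuntimeError("coalescent stalled")  # pragma: no cover
        t = t_next
        if t_next == t_act:
            _, leaf, deme = pending[pend_iter]
            active[deme if not merged else 0].append(leaf)
            pend_iter += 1
        elif t_next == t_merge:
            active[0].extend(active[1])
            active[1] = []
            merged = True
        else:
            lineages = active[coal_deme]
            i, j = rng.choice(len(lineages), size=2, replace=False)
            a, b = lineages[i], lineages[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            time[node] = t
            active[coal_deme] = [x for x in lineages if x not in (a, b)]
            active[coal_deme].append(node)

    return Genealogy(
        n_leaves=n, parent=parent, time=time, leaf_labels=leaf_labels
    )


# ---------------------------------------------------------------------------
# mutation


def _mutate(
    gen: Genealogy,
    mu: float,
    L: int,
    gen_time: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Drop finite-sites JC mutations on a genealogy.

    Returns (sorted touched site positions, leaf states at those sites
    as an (n_leaves, n_sites) uint8 matrix of base codes, root base per
    touched site).  Sites never hit carry the root base everywhere and
    are omitted.
    """
    rate_per_gen = mu * gen_time * L
    lengths = gen.branch_lengths()
    if lengths.max(initial=0.0) * rate_per_gen > 0.5 * L:
        warnings.warn("expected mutations per branch exceed L/2: saturation")
    children = gen.children()
    root_base: dict[int, int] = {}
    state: dict[int, int] = {}
    leaf_state: list[dict[int, int]] = [dict() for _ in range(gen.n_leaves)]

    # iterative DFS with undo records so `state` is shared, not copied
    stack: list[tuple[int, bool, list[tuple[int, int | None]]]] = [
        (gen.root, False, [])
    ]
    while stack:
        node, done, undo = stack.pop()
        if done:
            for site, prev in reversed(undo):
                if prev is None:
                    del state[site]
                else:
                    state[site] = prev
            continue
        undo_rec: list[tuple[int, int | None]] = []
        if node != gen.root:
            n_mut = rng.poisson(rate_per_gen * lengths[node])
            for _ in range(n_mut):
                site = int(rng.integers(L))
                if site not in root_base:
                    root_base[site] = int(rng.integers(4))
                cur = state.get(site, root_base[site])
                new = int(rng.integers(3))
                if new >= cur:
                    new += 1
                undo_rec.append((site, state.get(site)))
                state[site] = new
        if node < gen.n_leaves:
            leaf_state[node] = dict(state)
            for site, prev in reversed(undo_rec):
                if prev is None:
                    del state[site]
                else:
                    state[site] = prev
        else:
            stack.append((node, True, undo_rec))
            for child in children[node]:
                stack.append((child, False, []))

    positions = np.array(sorted(root_base), dtype=np.int64)
    mat = np.empty((gen.n_leaves, positions.size), dtype=np.uint8)
    for j, site in enumerate(positions):
        mat[:, j] = root_base[site]
    pos_index = {int(site): j for j, site in enumerate(positions)}
    for leaf, diffs in enumerate(leaf_state):
        for site, base in diffs.items():
            mat[leaf, pos_index[site]] = base
    return positions, mat, root_base


def simulate_variants(
    gen: Genealogy,
    mu: float,
    L: int = DEFAULT_LOCUS_LENGTH,
    gen_time: float = DEFAULT_GEN_TIME,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutated leaf states at touched sites only (fast path).

    Every diversity and differentiation statistic in this package
    depends only on variable columns, so reference-table construction
    uses this sparse form instead of materialising full alignments.
    """
    rng = np.random.default_rng(rng)
    positions, mat, _ = _mutate(gen, mu, L, gen_time, rng)
    return positions, mat


def drop_mutations(
    gen: Genealogy,
    mu: float,
    L: int = DEFAULT_LOCUS_LENGTH,
    gen_time: float = DEFAULT_GEN_TIME,
    rng: np.random.Generator | int | None = None,
    id_prefix: str = "sim",
) -> Alignment:
    """Drop mutations and materialise a full-length alignment.

    The ancestral sequence is drawn uniformly at the root; leaf ids are
    ``{prefix}_{group}_{index}``.
    """
    rng = np.random.default_rng(rng)
    positions, mat, root_base = _mutate(gen, mu, L, gen_time, rng)
    root_seq = rng.integers(0, 4, size=L).astype(np.uint8)
    for site, base in root_base.items():
        root_seq[site] = base
    ids = []
    counter: dict[str, int] = {}
    for label in gen.leaf_labels:
        counter[label] = counter.get(label, 0) + 1
        ids.append(f"{id_prefix}_{label}_{counter[label]}")
    seqs = []
    for leaf in range(gen.n_leaves):
        seq = root_seq.copy()
        seq[positions] = mat[leaf]
        seqs.append("".join(_DECODE[seq]))
    return Alignment(ids=tuple(ids), sequences=tuple(seqs))


# ---------------------------------------------------------------------------
# dataset-level convenience


def model_from_params(
    topology: str,
    params: dict[str, float],
    L: int = DEFAULT_LOCUS_LENGTH,
    gen_time: float = DEFAULT_GEN_TIME,
) -> DemographicModel:
    return DemographicModel(
        topology=topology,
        n_anc=params["n_anc"],
        mu=params["mu"],
        n_sic=params.get("n_sic"),
        t_div=params.get("t_div"),
        L=L,
        gen_time=gen_time,
    )


def simulate_dataset(
    topology: str,
    priors: PriorSet,
    sampling: SamplingConfig,
    rng: np.random.Generator | int | None = None,
    L: int = DEFAULT_LOCUS_LENGTH,
    gen_time: float = DEFAULT_GEN_TIME,
) -> tuple[GroupedAlignment, dict[str, float]]:
    """One prior draw -> one genealogy -> one mutated grouped alignment."""
    rng = np.random.default_rng(rng)
    params = priors.draw(rng)
    model = model_from_params(topology, params, L=L, gen_time=gen_time)
    gen = simulate_genealogy(model, sampling, rng)
    aln = drop_mutations(gen, model.mu, model.L, model.gen_time, rng)
    partition = {
        sampling.label_a: tuple(aln.ids[: sampling.n_a]),
        sampling.label_b: tuple(aln.ids[sampling.n_a:]),
    }
    ages = {
        **{sid: sampling.age_a for sid in partition[sampling.label_a]},
        **{sid: sampling.age_b for sid in partition[sampling.label_b]},
    }
    grouped = GroupedAlignment(alignment=aln, partition=partition, ages=ages)
    return grouped, params
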