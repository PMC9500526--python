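"""Synthetic fixtures: structured alignments, metadata, pseudo-observations.

Everything downstream of sequencing can be exercised without any real
data: the coalescent simulator provides grouped heterochronous
alignments at controlled differentiation levels, and a packaged
metadata table mirrors the study design this package was built around
(36 ancient mtDNA samples from five Sicilian localities in seven
locality-by-culture groups).  Alignment fixtures are generated on
demand from pinned seeds rather than shipped as files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import abc_rf, coalescent
from .seq_io import GroupedAlignment, SampleTable, read_metadata

#: fixed parameter rungs for the two-deme generator; the "low" rung is
#: panmixia (a single deme), "high" is a deep split with a small
#: diverged deme so drift pushes PhiST well above 0.3.
RUNGS: dict[str, dict] = {
    "low": {"topology": "continuity", "n_anc": 1000.0},
    "medium": {
        "topology": "discontinuity",
        "n_anc": 1000.0,
        "n_sic": 1000.0,
        "t_div": 20_000.0,
    },
    "high": {
        "topology": "discontinuity",
        "n_anc": 1000.0,
        "n_sic": 200.0,
        "t_div": 100_000.0,
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Two-deme generator settings: sizes, locus, rung, rate, seed."""

    seed: int
    n_a: int = 8
    n_b: int = 17
    L: int = coalescent.DEFAULT_LOCUS_LENGTH
    rung: str = "medium"
    mu: float = 2e-8
    age_a: float = 3500.0
    age_b: float = 2450.0

    def __post_init__(self) -> None:
        if self.rung not in RUNGS:
            raise ValueError(f"rung must be one of {sorted(RUNGS)}")
        if min(self.n_a, self.n_b, self.L) <= 0 or self.mu <= 0:
            raise ValueError("sizes, locus length and rate must be positive")


def make_structured_alignment(cfg: SyntheticConfig) -> GroupedAlignment:
    """Simulate a two-group dataset at the configured divergence rung."""
    rung = RUNGS[cfg.rung]
    model = coalescent.DemographicModel(
        topology=rung["topology"],
        n_anc=rung["n_anc"],
        n_sic=rung.get("n_sic"),
        t_div=rung.get("t_div"),
        mu=cfg.mu,
        L=cfg.L,
    )
    sampling = coalescent.SamplingConfig(
        n_a=cfg.n_a, age_a=cfg.age_a, n_b=cfg.n_b, age_b=cfg.age_b
    )
    rng = np.random.default_rng(cfg.seed)
    gen = coalescent.simulate_genealogy(model, sampling, rng)
    aln = coalescent.drop_mutations(gen, model.mu, model.L, model.gen_time, rng)
    partition = {
        sampling.label_a: tuple(aln.ids[: sampling.n_a]),
        sampling.label_b: tuple(aln.ids[sampling.n_a:]),
    }
    ages = {
        **{s: sampling.age_a for s in partition[sampling.label_a]},
        **{s: sampling.age_b for s in partition[sampling.label_b]},
    }
    return GroupedAlignment(alignment=aln, partition=partition, ages=ages)


def realized_phi(ga: GroupedAlignment) -> float:
    """Realised pairwise PhiST between the two groups of a dataset."""
    return float(abc_rf.summary_vector(ga).values[-1])


def make_pseudo_observed(
    topology: str,
    params: dict[str, float],
    sampling: coalescent.SamplingConfig | None = None,
    seed: int | None = None,
    L: int = coalescent.DEFAULT_LOCUS_LENGTH,
    gen_time: float = coalescent.DEFAULT_GEN_TIME,
) -> GroupedAlignment:
    """One dataset at explicit (known-truth) parameter values."""
    sampling = sampling or coalescent.SamplingConfig()
    model = coalescent.model_from_params(topology, params, L=L, gen_time=gen_time)
    rng = np.random.default_rng(seed)
    gen = coalescent.simulate_genealogy(model, sampling, rng)
    aln = coalescent.drop_mutations(gen, model.mu, model.L, model.gen_time, rng)
    partition = {
        sampling.label_a: tuple(aln.ids[: sampling.n_a]),
        sampling.label_b: tuple(aln.ids[sampling.n_a:]),
    }
    return GroupedAlignment(alignment=aln, partition=partition)


def make_table1_fixture() -> SampleTable:
    """Packaged per-sample metadata for the 36 ancient individuals.

    Adds a ``group`` column combining locality and culture/period
    (seven groups, e.g. ``Baucina_Sicanian``) and the midpoint age in
    years BP parsed from the printed date interval.
    """
    with resources.as_file(
        resources.files("mitostruct.data") / "table1.csv"
    ) as path:
        table = read_metadata(
            path,
            schema={
                "id": "sample_id",
                "site": "locality",
                "date": "estimated_date",
            },
        )
    locality = table.data["site"]
    culture = table.data["culture_period"].str.replace(" ", "_")
    table.data["group"] = locality + "_" + culture
    return table


_MACRO_POOL = ("H", "HV", "V", "T", "J", "U", "K", "I", "W", "X", "L3")


def synthetic_metadata(
    ga: GroupedAlignment, seed: int | None = None
) -> SampleTable:
    """Table-style metadata for a simulated grouped alignment.

    Haplogroup labels are synthetic: each distinct haplotype receives a
    random macro class with a numeric subclade suffix (e.g. ``T2``), so
    frequency-based analyses can run on simulator output.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    aln = ga.alignment
    _, inverse = np.unique(list(aln.sequences), return_inverse=True)
    labels = {}
    for hap in np.unique(inverse):
        macro = _MACRO_POOL[int(rng.integers(len(_MACRO_POOL)))]
        labels[int(hap)] = f"{macro}{int(rng.integers(1, 10))}"
    hap_by_id = {
        sid: labels[int(inverse[i])] for i, sid in enumerate(aln.ids)
    }
    rows = []
    for group, members in ga.partition.items():
        for sid in members:
            rows.append(
                {
                    "id": sid,
                    "group": group,
                    "site": group,
                    "culture_period": group,
                    "age_bp": ga.ages.get(sid),
                    "haplogroup": hap_by_id[sid],
                }
            )
    return SampleTable(pd.DataFrame(rows))
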