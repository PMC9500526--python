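"""End-to-end orchestration: frequencies -> PCA -> FST/AMOVA -> MDS -> ABC.

A single YAML config drives the full analysis; a master seed fans out
deterministically to named stage seeds (hash of stage name and seed),
so deterministic stages are bit-stable and stochastic stages are
reproducible.  Outputs are UTF-8 CSV/JSON plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_rf, coalescent, differentiation, haplogroups, seq_io

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def priors_from_dict(mapping: dict) -> dict[str, coalescent.PriorSet]:
    """Parse a {topology: {param: {dist, low, high}}} mapping."""
    out = {}
    for topology, params in mapping.items():
        priors = {
            name: coalescent.Prior(
                dist=str(p["dist"]), low=float(p["low"]), high=float(p["high"])
            )
            for name, p in params.items()
        }
        out[topology] = coalescent.PriorSet(topology=topology, priors=priors)
    return out


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    alignment: Path
    metadata: Path
    outdir: Path
    seed: int = 0
    group_field: str = "group"
    schema: dict = field(default_factory=dict)
    missing_policy: str = "complete"
    n_perm: int = 10_000
    mds_k: int = 2
    abc: dict | None = None  # keys: observed (2 labels), n_sims_per_model,
    #                          n_trees, L, gen_time, sampling, priors (path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        cfg = cls(
            alignment=base / raw["alignment"],
            metadata=base / raw["metadata"],
            outdir=base / raw.get("outdir", "out"),
            seed=int(raw.get("seed", 0)),
            group_field=raw.get("group_field", "group"),
            schema=raw.get("schema", {}) or {},
            missing_policy=raw.get("missing_policy", "complete"),
            n_perm=int(raw.get("n_perm", 10_000)),
            mds_k=int(raw.get("mds_k", 2)),
            abc=raw.get("abc"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.alignment, self.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.abc:
            prior_path = self.abc.get("priors")
            if prior_path and not (Path(self.metadata).parent / prior_path).exists() \
                    and not Path(prior_path).exists():
                raise FileNotFoundError(f"ABC prior file not found: {prior_path}")

    def content_hash(self) -> str:
        payload = {
            "alignment": str(self.alignment),
            "metadata": str(self.metadata),
            "seed": self.seed,
            "group_field": self.group_field,
            "schema": self.schema,
            "missing_policy": self.missing_policy,
            "n_perm": self.n_perm,
            "mds_k": self.mds_k,
            "abc": self.abc,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``cfg.outdir``.

    Returns the manifest dict.  A stage failure aborts with the stage
    named; artifacts already written are retained and the manifest
    marks the stage that failed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mitostruct",
        "version": _pkg_version("mitostruct"),
        "config_hash": cfg.content_hash(),
        "master_seed": cfg.seed,
        "stage_seeds": {},
        "stages": {},
        "artifacts": [],
    }

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path)
        manifest["artifacts"].append(name)

    current = "load"
    try:
        aln = seq_io.read_fasta_alignment(cfg.alignment)
        table = seq_io.read_metadata(cfg.metadata, schema=cfg.schema or None)
        grouped = seq_io.build_grouped(aln, table, group_field=cfg.group_field)
        manifest["stages"]["load"] = "ok"

        current = "frequencies"
        freq = haplogroups.frequency_table(
            table, group_field=cfg.group_field
        )
        _emit("haplogroup_counts.csv", freq.counts)
        _emit("haplogroup_frequencies.csv", freq.frequencies)
        manifest["stages"][current] = "ok"

        current = "pca"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = haplogroups.pca_frequencies(freq)
        _emit("pca_scores.csv", pca.scores)
        _emit("pca_loadings.csv", pca.loadings)
        _emit(
            "pca_explained.csv",
            pd.DataFrame(
                {"explained_variance_ratio": pca.explained_variance_ratio},
                index=pca.scores.columns,
            ),
        )
        manifest["stages"][current] = "ok"

        current = "distances"
        dist = differentiation.grouped_difference_matrix(grouped)
        _emit("difference_matrix.csv", dist.to_frame())
        manifest["stages"][current] = "ok"

        current = "fst"
        multi = {
            g: m for g, m in grouped.partition.items() if len(m) >= 2
        }
        dropped = sorted(set(grouped.partition) - set(multi))
        if dropped:
            logger.warning("singleton groups excluded from FST/AMOVA: %s", dropped)
        fst = differentiation.pairwise_fst(dist, multi)
        _emit("pairwise_fst.csv", fst.to_frame())
        manifest["stages"][current] = "ok"

        current = "amova"
        res = differentiation.amova(
            dist, multi, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "amova")
        )
        amova_df = pd.DataFrame(
            [
                {
                    "df_among": res.df_among,
                    "df_within": res.df_within,
                    "ssd_among": res.ssd_among,
                    "ssd_within": res.ssd_within,
                    "ssd_total": res.ssd_total,
                    "sigma2_among": res.sigma2_among,
                    "sigma2_within": res.sigma2_within,
                    "phi_st": res.phi_st,
                    "p_value": res.p_value,
                    "p_se": res.p_se,
                    "n_perm": res.n_perm,
                }
            ]
        )
        _emit("amova.csv", amova_df.set_index(pd.Index(["groups"])))
        manifest["stages"][current] = "ok"

        current = "mds"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = differentiation.classical_mds(fst, k=cfg.mds_k)
        _emit("mds_coordinates.csv", coords)
        manifest["stages"][current] = "ok"

        if cfg.abc:
            current = "abc"
            manifest["stage_seeds"]["abc"] = stage_seed(cfg.seed, "abc")
            result = _run_abc(cfg, grouped, out, manifest)
            (out / "model_choice.json").write_text(
                json.dumps(result.to_dict(), indent=2)
            )
            manifest["artifacts"].append("model_choice.json")
            manifest["stages"][current] = "ok"
    except Exception as exc:
        manifest["stages"][current] = f"failed: {exc}"
        _write_manifest()
        raise StageError(current, exc) from exc

    manifest["stage_seeds"]["amova"] = stage_seed(cfg.seed, "amova")
    _write_manifest()
    return manifest


def _run_abc(
    cfg: RunConfig,
    grouped: seq_io.GroupedAlignment,
    out: Path,
    manifest: dict,
) -> abc_rf.ModelChoiceResult:
    abc_cfg = cfg.abc or {}
    observed_labels = abc_cfg.get("observed") or grouped.group_labels[:2]
    if len(observed_labels) != 2:
        raise ValueError("abc.observed must name exactly 2 groups")
    sub = seq_io.GroupedAlignment(
        alignment=grouped.alignment,
        partition={g: grouped.partition[g] for g in observed_labels},
        ages=grouped.ages,
    )
    observed = abc_rf.summary_vector(sub, cfg.missing_policy)

    prior_path = abc_cfg.get("priors")
    if prior_path:
        p = Path(prior_path)
        if not p.exists():
            p = Path(cfg.metadata).parent / prior_path
        priors = priors_from_dict(yaml.safe_load(p.read_text()))
    else:
        priors = {
            t: coalescent.default_priors(t)
            for t in ("continuity", "discontinuity")
        }
    samp = abc_cfg.get("sampling", {})
    sampling = coalescent.SamplingConfig(
        n_a=int(samp.get("n_a", len(sub.partition[observed_labels[0]]))),
        age_a=float(samp.get("age_a", 3500.0)),
        n_b=int(samp.get("n_b", len(sub.partition[observed_labels[1]]))),
        age_b=float(samp.get("age_b", 2450.0)),
        label_a=observed_labels[0],
        label_b=observed_labels[1],
    )
    table = abc_rf.build_reference_table(
        priors,
        sampling,
        n_sims_per_model=int(abc_cfg.get("n_sims_per_model", 5000)),
        seed=stage_seed(cfg.seed, "abc"),
        L=int(abc_cfg.get("L", coalescent.DEFAULT_LOCUS_LENGTH)),
        gen_time=float(abc_cfg.get("gen_time", coalescent.DEFAULT_GEN_TIME)),
    )
    table.to_frame().to_csv(out / "reference_table.csv", index=False)
    table.params.to_csv(out / "reference_params.csv", index=False)
    manifest["artifacts"] += ["reference_table.csv", "reference_params.csv"]

    forest = abc_rf.ModelChoiceForest(
        table,
        n_trees=int(abc_cfg.get("n_trees", 500)),
        seed=stage_seed(cfg.seed, "abc-rf"),
    )
    lda_df = pd.DataFrame(
        {
            "model": table.labels,
            "lda1": forest.lda.transform(table.X).ravel(),
        }
    )
    lda_df.to_csv(out / "lda_projections.csv", index=False)
    manifest["artifacts"].append("lda_projections.csv")
    return forest.select(observed)
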