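"""ABC model choice with random forests (ABC-RF).

Model choice between demographic hypotheses is cast as a
classification problem: a reference table of summary statistics is
simulated under each model's priors, a random forest is trained to
predict the model label from the statistics, and the observed data are
classified.  Confidence comes from the forest's out-of-bag (OOB)
confusion matrix; the posterior probability of the selected model is
estimated as one minus the expected misclassification probability at
the observed point, obtained from a regression forest fitted to the
OOB misclassification indicator.  Following standard ABC-RF practice,
the one Fisher linear-discriminant axis (two models give M-1 = 1 axis)
is appended to the summary statistics as an extra feature.

The summary vector holds, per deme, the number of haplotypes K,
haplotype diversity H, segregating sites S, Tajima's D and mean
pairwise differences Pi, plus the pairwise PhiST between the demes —
11 statistics.  D is imputed as 0 (flagged) wherever it is undefined,
since forest features cannot be missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import coalescent, differentiation, diversity
from .seq_io import GroupedAlignment

N_BASE_FEATURES = 11


def feature_names(label_a: str = "A", label_b: str = "B") -> tuple[str, ...]:
    per_deme = ("K", "H", "S", "D", "Pi")
    return tuple(
        f"{stat}_{label}" for label in (label_a, label_b) for stat in per_deme
    ) + ("phi_st",)


@dataclass(frozen=True)
class SummaryStatVector:
    """11 summary statistics for a two-deme dataset."""

    values: np.ndarray
    names: tuple[str, ...]
    d_imputed: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.names),):
            raise ValueError("summary vector length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("summary vector contains non-finite values")


def _deme_stats(mat: np.ndarray) -> tuple[list[float], bool]:
    vec = diversity.stats_from_codes(mat)
    d = None
    if vec.n >= 4 and vec.S > 0:
        d = diversity.tajimas_d(vec.S, vec.Pi, vec.n)
    imputed = d is None
    return [float(vec.K), vec.H, float(vec.S), d or 0.0, vec.Pi], imputed


def summary_from_codes(mat: np.ndarray, n_a: int) -> SummaryStatVector:
    """Summary vector from an encoded (n, sites) matrix, first n_a rows
    being deme A.  Statistics depend on variable columns only, so the
    matrix may be restricted to segregating sites."""
    n = mat.shape[0]
    stats_a, imp_a = _deme_stats(mat[:n_a])
    stats_b, imp_b = _deme_stats(mat[n_a:])
    diffs = diversity._pairwise_diff_counts(mat)
    labels = np.r_[np.zeros(n_a, int), np.ones(n - n_a, int)]
    phi = differentiation._phi_components(diffs, labels, 2)[5]
    return SummaryStatVector(
        values=np.array([*stats_a, *stats_b, phi], dtype=float),
        names=feature_names(),
        d_imputed=(imp_a, imp_b),
    )


def summary_vector(
    ga: GroupedAlignment, missing_policy: str = "complete"
) -> SummaryStatVector:
    """Summary vector for a two-group alignment (deme order = partition
    order); delegates to the diversity and differentiation modules."""
    if len(ga.partition) != 2:
        raise ValueError("summary vector requires exactly 2 groups")
    label_a, label_b = ga.group_labels
    per_deme = []
    imputed = []
    for label in (label_a, label_b):
        sub = ga.group_alignment(label)
        vec = diversity.within_group_stats(sub.sequences, missing_policy)
        d = None
        if vec.n >= 4 and vec.S > 0:
            d = diversity.tajimas_d(vec.S, vec.Pi, vec.n)
        imputed.append(d is None)
        per_deme.extend([float(vec.K), vec.H, float(vec.S), d or 0.0, vec.Pi])
    dist = differentiation.grouped_difference_matrix(ga)
    phi = differentiation.pairwise_fst(dist, ga.partition).values[0, 1]
    return SummaryStatVector(
        values=np.array([*per_deme, phi], dtype=float),
        names=feature_names(label_a, label_b),
        d_imputed=(imputed[0], imputed[1]),
    )


@dataclass
class ReferenceTable:
    """Simulated summary statistics with model labels and parameter log."""

    X: np.ndarray
    labels: np.ndarray
    params: pd.DataFrame = field(repr=False)
    feature_names: tuple[str, ...] = feature_names()

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree in row count")
        if not np.isfinite(self.X).all():
            raise ValueError("reference table contains non-finite cells")

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "model", self.labels)
        return df


def _simulate_row(
    priors: coalescent.PriorSet,
    sampling: coalescent.SamplingConfig,
    rng: np.random.Generator,
    L: int,
    gen_time: float,
) -> tuple[np.ndarray, dict[str, float], tuple[bool, bool]]:
    params = priors.draw(rng)
    model = coalescent.model_from_params(
        priors.topology, params, L=L, gen_time=gen_time
    )
    gen = coalescent.simulate_genealogy(model, sampling, rng)
    _, mat = coalescent.simulate_variants(gen, model.mu, L, gen_time, rng)
    vec = summary_from_codes(mat, sampling.n_a)
    return vec.values, params, vec.d_imputed


def build_reference_table(
    priors_by_model: dict[str, coalescent.PriorSet],
    sampling: coalescent.SamplingConfig,
    n_sims_per_model: int,
    seed: int | None = None,
    L: int = coalescent.DEFAULT_LOCUS_LENGTH,
    gen_time: float = coalescent.DEFAULT_GEN_TIME,
    max_retries: int = 10,
) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` datasets per model and summarise.

    ``priors_by_model`` maps a model label (usually the topology name)
    to its :class:`~mitostruct.coalescent.PriorSet`; each prior set
    carries its own topology.  Labels are balanced by construction; a
    simulation violating an invariant is retried on a fresh RNG
    substream (at most ``max_retries`` times) with a warning.
    """
    if n_sims_per_model < 100:
        warnings.warn("fewer than 100 simulations per model is very coarse")
    rng = np.random.default_rng(seed)
    rows, labels, logs = [], [], []
    for label, priors in priors_by_model.items():
        for i in range(n_sims_per_model):
            for attempt in range(max_retries + 1):
                try:
                    values, params, d_imp = _simulate_row(
                        priors, sampling, rng, L, gen_time
                    )
                    break
                except (ValueError, RuntimeError) as exc:
                    if attempt == max_retries:
                        raise
                    warnings.warn(f"simulation retry ({label} #{i}): {exc}")
            rows.append(values)
            labels.append(label)
            logs.append({"model": label, **params,
                         "d_imputed_a": d_imp[0], "d_imputed_b": d_imp[1]})
    return ReferenceTable(
        X=np.vstack(rows),
        labels=np.array(labels),
        params=pd.DataFrame(logs),
        feature_names=feature_names(sampling.label_a, sampling.label_b),
    )


# ---------------------------------------------------------------------------
# LDA augmentation


def fit_lda(X: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(solver="eigen")
    try:
        lda.fit(X, labels)
    except LinAlgError:
        warnings.warn("singular within-class scatter; ridge-regularised LDA")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-8)
        lda.fit(X, labels)
    return lda


def augment_with_lda(
    table: ReferenceTable, observed: SummaryStatVector
) -> tuple[np.ndarray, np.ndarray, LinearDiscriminantAnalysis]:
    """Append the Fisher LDA axis (fitted on the table only) as an
    extra feature to both table rows and the observation."""
    lda = fit_lda(table.X, table.labels)
    table_proj = lda.transform(table.X)
    obs_proj = lda.transform(observed.values.reshape(1, -1))
    X_aug = np.hstack([table.X, table_proj])
    obs_aug = np.concatenate([observed.values, obs_proj.ravel()])
    return X_aug, obs_aug, lda


# ---------------------------------------------------------------------------
# random-forest model choice


@dataclass(frozen=True)
class ModelChoiceResult:
    """Votes, OOB confusion, classification errors, posterior."""

    selected: str
    votes: dict[str, int]
    n_trees: int
    oob_confusion: pd.DataFrame
    classification_error: dict[str, float]
    prior_error_rate: float
    posterior_probability: float
    lda_observed: float

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "votes": self.votes,
            "n_trees": self.n_trees,
            "oob_confusion": self.oob_confusion.to_dict(),
            "classification_error": self.classification_error,
            "prior_error_rate": self.prior_error_rate,
            "posterior_probability": self.posterior_probability,
            "lda_observed": self.lda_observed,
        }


class ModelChoiceForest:
    """A fitted ABC-RF classifier reusable across many observations.

    Fitting is the expensive step (two forests over the full reference
    table); selection for a single observed vector is then cheap, which
    is what calibration experiments over hundreds of pseudo-observed
    datasets need.
    """

    def __init__(
        self,
        table: ReferenceTable,
        n_trees: int = 500,
        seed: int | None = None,
    ) -> None:
        if n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        self.table = table
        self.n_trees = n_trees
        self.lda = fit_lda(table.X, table.labels)
        X_aug = np.hstack([table.X, self.lda.transform(table.X)])
        self._X_aug = X_aug
        self.classifier = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            n_jobs=1,
            random_state=None if seed is None else int(seed) % 2**31,
        )
        self.classifier.fit(X_aug, table.labels)
        self._compute_oob()
        self.error_forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            n_jobs=1,
            random_state=None if seed is None else (int(seed) + 1) % 2**31,
        )
        self.error_forest.fit(
            X_aug[self._oob_available], self._oob_misclassified.astype(float)
        )

    def _compute_oob(self) -> None:
        proba = self.classifier.oob_decision_function_
        available = ~np.isnan(proba).any(axis=1)
        if not available.all():
            warnings.warn(
                f"{(~available).sum()} row(s) never out-of-bag; excluded "
                "from the confusion matrix"
            )
        classes = self.classifier.classes_
        pred = classes[np.argmax(proba[available], axis=1)]
        true = self.table.labels[available]
        self._oob_available = available
        self._oob_misclassified = pred != true
        conf = pd.crosstab(
            pd.Series(true, name="true"), pd.Series(pred, name="oob_predicted")
        ).reindex(index=classes, columns=classes, fill_value=0)
        self.oob_confusion = conf
        self.classification_error = {
            m: 1.0 - conf.loc[m, m] / conf.loc[m].sum() for m in classes
        }
        self.prior_error_rate = float(self._oob_misclassified.mean())

    # -- observation-level API ------------------------------------------

    def augment(self, observed: np.ndarray) -> np.ndarray:
        obs2d = np.atleast_2d(observed)
        return np.hstack([obs2d, self.lda.transform(obs2d)])

    def predict(self, observed: np.ndarray) -> np.ndarray:
        """Majority-vote model label(s) for raw 11-statistic vectors."""
        return self.classifier.predict(self.augment(observed))

    def votes(self, observed: np.ndarray) -> dict[str, int]:
        obs_aug = self.augment(observed)
        classes = self.classifier.classes_
        counts = dict.fromkeys(classes, 0)
        for tree in self.classifier.estimators_:
            idx = int(tree.predict(obs_aug)[0])
            counts[classes[idx]] += 1
        return {str(k): v for k, v in counts.items()}

    def select(self, observed: SummaryStatVector | np.ndarray) -> ModelChoiceResult:
        values = (
            observed.values
            if isinstance(observed, SummaryStatVector)
            else np.asarray(observed, dtype=float)
        )
        obs_aug = self.augment(values)
        votes = self.votes(values)
        top = max(votes.values())
        winners = sorted(m for m, v in votes.items() if v == top)
        if len(winners) > 1:
            warnings.warn(f"vote tie between {winners}; lexicographic first")
        selected = winners[0]
        perr = float(np.clip(self.error_forest.predict(obs_aug)[0], 0.0, 1.0))
        return ModelChoiceResult(
            selected=selected,
            votes=votes,
            n_trees=self.n_trees,
            oob_confusion=self.oob_confusion,
            classification_error={
                str(k): float(v) for k, v in self.classification_error.items()
            },
            prior_error_rate=self.prior_error_rate,
            posterior_probability=1.0 - perr,
            lda_observed=float(obs_aug[0, -1]),
        )


def train_and_select(
    table: ReferenceTable,
    observed: SummaryStatVector,
    n_trees: int = 500,
    seed: int | None = None,
) -> ModelChoiceResult:
    """One-shot convenience: fit the ABC-RF forests and classify one
    observed summary vector."""
    return ModelChoiceForest(table, n_trees=n_trees, seed=seed).select(observed)
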