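"""Macro-haplogroup collapsing, per-group frequency tables, and PCA.

Fine haplogroup labels such as ``T2b3+151`` are collapsed to
macro-haplogroup classes (``T``) by longest-prefix match against an
ordered scheme, after stripping diagnostic-position suffixes
(``+151``, ``+16,311`` and the like).  Frequency tables feed a PCA on
group-wise relative frequencies, the standard visual summary of
mtDNA haplogroup composition across populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .seq_io import SampleTable

logger = logging.getLogger(__name__)

#: Western-Eurasian + African macro-haplogroups, longest prefix wins
#: ("HV0a" -> HV, not H; "H1e8" -> H; "V25" -> V).
DEFAULT_MACRO_SCHEME: tuple[str, ...] = (
    "L0", "L1", "L2", "L3", "L4", "L5",
    "HV", "H", "V", "J", "T", "U", "K", "I", "W", "X", "N", "R", "M",
)


class HaplogroupError(ValueError):
    """A label that no macro class in the scheme matches."""


def collapse_to_macro(
    label: str, scheme: tuple[str, ...] = DEFAULT_MACRO_SCHEME
) -> str:
    """Collapse a fine haplogroup label to its macro-haplogroup.

    Suffix annotations after ``+`` (extra diagnostic positions, e.g.
    ``T2b3+151``, ``V+72at``) are stripped first; then the longest
    scheme prefix of the remainder is returned.  L sub-lineages not in
    the scheme fall back to the bare ``L`` class.  Unmatched labels
    raise rather than silently pooling into an "other" bin.
    """
    if not label or not str(label).strip():
        raise HaplogroupError("empty haplogroup label")
    stem = str(label).strip().split("+")[0].strip()
    best = ""
    for macro in scheme:
        if stem.startswith(macro) and len(macro) > len(best):
            best = macro
    if best:
        return best
    if stem.startswith("L"):
        return "L"
    raise HaplogroupError(f"haplogroup label {label!r} matches no macro class")


@dataclass(frozen=True)
class FrequencyTable:
    """Groups x macro-haplogroups count matrix with a frequency view."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def group_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.group_sizes, axis=0)


def frequency_table(
    table: SampleTable,
    scheme: tuple[str, ...] = DEFAULT_MACRO_SCHEME,
    group_field: str = "group",
) -> FrequencyTable:
    """Count macro-haplogroups per group.

    Every sample must carry a haplogroup label; an unmappable label
    propagates a :class:`HaplogroupError` naming the offender.
    """
    data = table.data
    if data["haplogroup"].isna().any():
        missing = data.loc[data["haplogroup"].isna(), "id"].tolist()
        raise HaplogroupError(f"samples without haplogroup label: {missing}")
    macros = data["haplogroup"].map(lambda h: collapse_to_macro(h, scheme))
    counts = (
        pd.crosstab(data[group_field], macros)
        .rename_axis(index="group", columns="macro")
    )
    # keep scheme order for the columns that occur
    order = [m for m in (*scheme, "L") if m in counts.columns]
    extra = [m for m in counts.columns if m not in order]
    return FrequencyTable(counts[order + extra].astype(int))


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame          # groups x components
    loadings: pd.DataFrame        # haplogroups x components
    explained_variance_ratio: np.ndarray


def pca_frequencies(
    freq: FrequencyTable,
    scale_unit_variance: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """PCA on group-wise relative haplogroup frequencies.

    Rows (groups) are observations; columns (macro-haplogroups) are
    variables, centred and optionally scaled to unit variance.
    All-constant columns are dropped with a warning.  Scores and
    loadings come back biplot-ready.
    """
    X = freq.frequencies
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 groups")
    variances = X.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant haplogroup columns: {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        # identical rows: nothing varies, every group sits at the origin
        warnings.warn("no varying haplogroup column; degenerate PCA")
        zeros = pd.DataFrame(
            0.0, index=freq.frequencies.index, columns=["PC1"]
        )
        return PcaResult(
            scores=zeros,
            loadings=pd.DataFrame(
                0.0, index=freq.frequencies.columns, columns=["PC1"]
            ),
            explained_variance_ratio=np.array([0.0]),
        )
    values = X.to_numpy(dtype=float)
    if scale_unit_variance:
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    max_rank = min(values.shape[0] - 1, values.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(values)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=X.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
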