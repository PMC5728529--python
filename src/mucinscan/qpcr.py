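"""qPCR relative-quantification chain: duplicate QC, primer efficiency,
reference-gene stability, delta-Ct, tissue profiles and group log2 fold
changes with linear-model testing.

The quantification model is the classic comparative-Ct scheme: within each
sample, the target's Ct is normalised by a reference gene
(delta-Ct = Ct_target - Ct_reference; lower delta-Ct = more transcript,
one cycle = one log2 unit at doubling efficiency).  Group effects are
log2 fold changes relative to the mean delta-Ct of the control/baseline
group, tested per gene (and tissue) with a one-way fixed-effects linear
model: each non-control group is contrasted against control using the
pooled residual variance, two-sided.

Reference-gene stability implements the four measures aggregated by the
RefFinder approach: the geNorm M-value, BestKeeper's raw Ct standard
deviation, the comparative delta-Ct measure, and a NormFinder-style
two-way-centred residual spread; genes are ranked per measure and the
aggregate rank is the geometric mean of the four ranks (lowest = most
stable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CtRecord

__all__ = [
    "GroupEffect",
    "collapse_duplicates",
    "efficiency_from_dilution",
    "stability_ranking",
    "delta_ct",
    "tissue_profile_matrix",
    "log2fc_vs_control",
]

logger = logging.getLogger(__name__)

DEFAULT_QC_LIMIT = 0.5
ALPHA = 0.05

_SAMPLE_KEYS = ["sample_id", "fish_id", "tissue", "group"]


@dataclass(frozen=True)
class GroupEffect:
    """log2 fold change of one group vs control for one gene and tissue."""

    gene: str
    tissue: str
    group: str
    log2fc: float
    p_value: float | None
    significant: bool


def _records_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def collapse_duplicates(
    records: Sequence[CtRecord],
    qc_limit: float = DEFAULT_QC_LIMIT,
    mode: str = "conventional",
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse technical duplicates to per-sample mean Ct with QC.

    In the default ``"conventional"`` mode a duplicate pair is retained when
    |Ct1 - Ct2| < ``qc_limit`` and discarded at >= ``qc_limit``; the
    ``"literal"`` mode applies the opposite rule (retain pairs differing by
    at least ``qc_limit``).  Singleton wells pass with a warning.  Returns
    the collapsed table (one row per sample x gene) and the QC log.
    """
    if mode not in ("conventional", "literal"):
        raise ValueError(f"unknown QC mode {mode!r}")
    frame = _records_frame(records)
    if frame.empty:
        return (
            pd.DataFrame(columns=_SAMPLE_KEYS + ["gene", "ct", "n_replicates"]),
            [],
        )
    qc_log: list[str] = []
    rows = []
    for key, grp in frame.groupby(_SAMPLE_KEYS + ["gene"], sort=True):
        if len(grp) > 2:
            raise ValueError(
                f"more than 2 replicates for sample {key[0]!r} gene {key[-1]!r}"
            )
        cts = grp["ct"].to_numpy(float)
        if len(cts) == 1:
            qc_log.append(
                f"singleton well: sample {key[0]} gene {key[-1]} (retained)"
            )
        else:
            diff = abs(cts[0] - cts[1])
            discard = diff >= qc_limit if mode == "conventional" else diff < qc_limit
            if discard:
                qc_log.append(
                    f"discarded pair: sample {key[0]} gene {key[-1]} "
                    f"|dCt| = {diff:.3f} ({mode} mode, limit {qc_limit})"
                )
                continue
        rows.append(dict(zip(_SAMPLE_KEYS + ["gene"], key), ct=float(cts.mean()),
                         n_replicates=len(cts)))
    return pd.DataFrame(rows, columns=_SAMPLE_KEYS + ["gene", "ct", "n_replicates"]), qc_log


def efficiency_from_dilution(series: Sequence[tuple[float, float]]) -> float:
    """Amplification efficiency from a dilution series.

    ``series`` is a sequence of (relative concentration, Ct) points, at
    least three.  Fits Ct = a + b * log10(concentration) by least squares
    and returns the amplification factor E = 10^(-1/b); perfect doubling
    gives 2.0.  A non-negative slope (Ct increasing with template) is an
    estimation error.
    """
    if len(series) < 3:
        raise ValueError("dilution series needs at least 3 points")
    conc = np.asarray([c for c, _ in series], dtype=float)
    ct = np.asarray([t for _, t in series], dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    slope, _intercept = np.polyfit(np.log10(conc), ct, 1)
    if slope >= 0:
        raise ValueError(
            f"slope {slope:.3f} >= 0: Ct does not decrease with concentration"
        )
    return float(10.0 ** (-1.0 / slope))


def stability_ranking(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate reference genes by four stability measures.

    ``collapsed`` is a collapsed Ct table (from :func:`collapse_duplicates`)
    restricted to the candidate reference genes.  Only samples in which
    every candidate was measured enter the comparison.  Returns one row per
    gene with columns ``genorm_m``, ``bestkeeper_sd``,
    ``comparative_dct_stability``, ``normfinder_stability``, the four ranks
    and ``aggregate_rank`` (geometric mean of ranks; lowest = most stable),
    sorted by aggregate rank.
    """
    pivot = collapsed.pivot_table(index="sample_id", columns="gene", values="ct")
    pivot = pivot.dropna(axis=0)
    genes = list(pivot.columns)
    if len(genes) < 2:
        raise ValueError("stability ranking needs at least 2 candidate genes")
    if len(pivot) < 3:
        raise ValueError(
            f"stability ranking needs >= 3 complete samples, got {len(pivot)}"
        )
    X = pivot.to_numpy(float)  # samples x genes

    def sd(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1))

    genorm, bestkeeper, comparative, normfinder = {}, {}, {}, {}
    # doubly centred residuals for the NormFinder-style measure
    resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + X.mean()
    for j, gene in enumerate(genes):
        pair_sds = [sd(X[:, j] - X[:, k]) for k in range(len(genes)) if k != j]
        genorm[gene] = float(np.mean(pair_sds))
        comparative[gene] = float(np.mean(pair_sds))
        bestkeeper[gene] = sd(X[:, j])
        normfinder[gene] = sd(resid[:, j])

    out = pd.DataFrame(
        {
            "genorm_m": genorm,
            "bestkeeper_sd": bestkeeper,
            "comparative_dct_stability": comparative,
            "normfinder_stability": normfinder,
        }
    ).loc[genes]
    if np.allclose(out.to_numpy(), 0.0):
        logger.warning("all stability measures are zero; ranks tie by gene order")
    for col in list(out.columns):
        # average ranks on ties (pairwise measures tie exactly for 2 genes);
        # the final stable sort resolves residual ties by gene order
        out[f"{col}_rank"] = out[col].rank(method="average")
    rank_cols = [c for c in out.columns if c.endswith("_rank")]
    out["aggregate_rank"] = np.exp(np.log(out[rank_cols]).mean(axis=1))
    out.index.name = "gene"
    return out.sort_values("aggregate_rank", kind="stable")


def delta_ct(collapsed: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Normalise collapsed Ct values by the reference gene, per sample.

    Returns a long table with ``delta_ct = Ct_target - Ct_reference`` for
    every non-reference gene.  Samples in which the reference was not
    measured are dropped and logged; a reference absent from the whole
    table is an error.
    """
    if reference_gene not in set(collapsed["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    ref = (
        collapsed[collapsed["gene"] == reference_gene]
        .set_index("sample_id")["ct"]
    )
    rows = []
    for sample_id, grp in collapsed[collapsed["gene"] != reference_gene].groupby(
        "sample_id", sort=True
    ):
        if sample_id not in ref.index:
            logger.warning(
                "sample %s lacks reference %s; dropped", sample_id, reference_gene
            )
            continue
        for _, row in grp.iterrows():
            rows.append(
                {
                    "sample_id": sample_id,
                    "fish_id": row["fish_id"],
                    "tissue": row["tissue"],
                    "group": row["group"],
                    "gene": row["gene"],
                    "delta_ct": float(row["ct"] - ref.loc[sample_id]),
                }
            )
    return pd.DataFrame(
        rows, columns=_SAMPLE_KEYS + ["gene", "delta_ct"]
    )


def tissue_profile_matrix(dct: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue matrix of inverted mean delta-Ct.

    Each cell is -(mean over fish of delta-Ct), so higher values mean more
    transcript.  Gene/tissue combinations with no measurement are left
    missing (NaN), not zero: an undetected transcript is absent, not at the
    reference level.
    """
    means = dct.groupby(["gene", "tissue"])["delta_ct"].mean()
    return (-means).unstack("tissue")


def _ols_group_contrasts(
    values: dict[str, np.ndarray], control: str
) -> dict[str, tuple[float, float | None]]:
    """One-way fixed-effects contrasts of each group vs control.

    Returns per non-control group (estimate, p) where the estimate is
    mean(group) - mean(control) and p is the two-sided t-test using the
    pooled residual variance of the full one-way model (identical to the
    OLS coefficient test under treatment coding).  Singleton groups get
    p = None.
    """
    k = len(values)
    n_total = sum(len(v) for v in values.values())
    dof = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in values.values())
    s2 = sse / dof if dof > 0 else 0.0
    ctrl = values[control]
    out: dict[str, tuple[float, float | None]] = {}
    for grp, v in values.items():
        if grp == control:
            continue
        est = float(v.mean() - ctrl.mean())
        if len(v) < 2:
            out[grp] = (est, None)
            continue
        se = math.sqrt(s2 * (1.0 / len(v) + 1.0 / len(ctrl))) if s2 > 0 else 0.0
        if se == 0.0:
            p = 1.0 if est == 0.0 else float(np.finfo(float).tiny)
        else:
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), dof))
            p = max(p, float(np.finfo(float).tiny))
        out[grp] = (est, p)
    return out


def log2fc_vs_control(
    dct: pd.DataFrame,
    control_group: str,
    alpha: float = ALPHA,
) -> list[GroupEffect]:
    """Group log2 fold changes vs the control/baseline group.

    Separately for each gene and tissue, fits a one-way linear model of
    delta-Ct on group and contrasts every group against ``control_group``
    (two-sided, pooled residual variance).  The log2 fold change is the
    negated delta-Ct contrast: log2fc = -(mean delta-Ct of group - mean
    delta-Ct of control), i.e. the mean over fish of -(delta-Ct_fish -
    control mean).  The control group itself is reported with log2fc
    exactly 0 and no p-value.  Singleton non-control groups get their
    effect but no p-value (logged).
    """
    effects: list[GroupEffect] = []
    for (gene, tissue), stratum in dct.groupby(["gene", "tissue"], sort=True):
        groups = {
            g: grp["delta_ct"].to_numpy(float)
            for g, grp in stratum.groupby("group", sort=True)
        }
        if control_group not in groups:
            raise ValueError(
                f"{gene}/{tissue}: control group {control_group!r} absent"
            )
        if len(groups[control_group]) < 2:
            raise ValueError(
                f"{gene}/{tissue}: control group needs >= 2 fish"
            )
        if len(groups) < 2:
            raise ValueError(f"{gene}/{tissue}: need at least 2 groups")
        contrasts = _ols_group_contrasts(groups, control_group)
        effects.append(
            GroupEffect(gene=gene, tissue=tissue, group=control_group,
                        log2fc=0.0, p_value=None, significant=False)
        )
        for grp in sorted(contrasts):
            est, p = contrasts[grp]
            if p is None:
                logger.warning(
                    "%s/%s group %s has one fish; effect reported without p",
                    gene, tissue, grp,
                )
            effects.append(
                GroupEffect(
                    gene=gene,
                    tissue=tissue,
                    group=grp,
                    log2fc=-est,
                    p_value=p,
                    significant=(p is not None and p < alpha),
                )
            )
    return effects


def effects_frame(effects: Sequence[GroupEffect]) -> pd.DataFrame:
    """Tabular form of :func:`log2fc_vs_control` output."""
    return pd.DataFrame([e.__dict__ for e in effects])
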