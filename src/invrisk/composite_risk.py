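"""Composite risk pooling, calibration binning and risk summaries.

The composite risk of a high-impact invasion for host tree t and insect
i pools the available submodels in logit space:

    R(t,i) = logit(Pbar..) + (1/N) * sum_m [logit(Phat_m) - logit(Pbar_m)]

where Phat_m is submodel m's predicted probability for the pair,
Pbar_m the proportion of high-impact pairs in the data used to fit
submodel m, Pbar.. the overall high-impact proportion, and N the number
of submodels (1-3) yielding a prediction for the pair. A pair that sits
at every submodel's baseline therefore scores exactly the overall
baseline. All pooling happens in logit units; probabilities are clamped
to [1e-300, 1 - 1e-15] before the logit so that extremely small but
meaningful risks survive un-clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census_io import Census, filter_low_documentation_hosts
from .exceptions import AvailabilityError, ValidationError
from .glm_core import inv_logit, logit
from .phylo import DatedTree, closest_native_host
from .submodels import (
    HOST_EVOLUTION_GUILDS,
    assign_congener_status,
    predict_guild_risk,
    published_congener_model,
    published_guild_model,
    published_host_traits_model,
)

__all__ = [
    "PROB_CLAMP",
    "CompositeContext",
    "CompositeRisk",
    "composite_risk",
    "compute_baselines",
    "bin_calibration",
    "risk_summary",
    "score_census",
]

#: Probabilities are clamped to this closed interval before the logit.
PROB_CLAMP = (1e-300, 1.0 - 1e-15)


def _clamped_logit(p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1]")
    if p < PROB_CLAMP[0] or p > PROB_CLAMP[1]:
        p = min(max(p, PROB_CLAMP[0]), PROB_CLAMP[1])
    return logit(p)


@dataclass(frozen=True)
class CompositeContext:
    """Baselines used by the composite pooling."""

    submodel_baselines: Mapping[str, float]
    overall_baseline: float

    def __post_init__(self) -> None:
        for name, p in {**dict(self.submodel_baselines),
                        "overall": self.overall_baseline}.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"baseline {name}={p} outside [0, 1]")
            if p in (0.0, 1.0):
                warnings.warn(
                    f"baseline {name} is exactly {p}; it will be clamped "
                    "before the logit", stacklevel=3)


@dataclass(frozen=True)
class CompositeRisk:
    insect_id: str
    host_id: str
    risk_logit: float
    contributions: Mapping[str, float] = field(default_factory=dict)

    @property
    def risk_prob(self) -> float:
        return float(inv_logit(self.risk_logit))

    @property
    def n_available(self) -> int:
        return len(self.contributions)


def composite_risk(
    predictions: Mapping[str, float],
    context: CompositeContext,
    insect_id: str = "",
    host_id: str = "",
) -> CompositeRisk:
    """Pool the available submodel predictions for one pair."""
    if not predictions:
        raise AvailabilityError(
            f"no submodel predictions for pair ({insect_id}, {host_id})")
    deviations = []
    for name, p_hat in predictions.items():
        if name not in context.submodel_baselines:
            raise AvailabilityError(f"no baseline for submodel {name!r}")
        deviations.append(
            _clamped_logit(p_hat) - _clamped_logit(context.submodel_baselines[name]))
    r = _clamped_logit(context.overall_baseline) + float(np.mean(deviations))
    return CompositeRisk(insect_id=insect_id, host_id=host_id, risk_logit=r,
                         contributions=dict(predictions))


def compute_baselines(
    high_impact: Sequence[int] | np.ndarray,
    submodel_masks: Mapping[str, Sequence[bool]],
) -> CompositeContext:
    """Baselines from data: per-submodel and overall high-impact rates."""
    y = np.asarray(high_impact, dtype=float)
    if y.size == 0:
        raise ValidationError("no observations")
    def rate(values: np.ndarray, label: str) -> float:
        p = float(values.mean())
        if p in (0.0, 1.0):
            # half-a-count continuity correction: a degenerate observed
            # rate would otherwise send the baseline logit to +/-inf
            adj = 1.0 / (2 * len(values))
            warnings.warn(
                f"baseline {label} is exactly {p:g}; using the "
                f"continuity-corrected rate {adj if p == 0 else 1 - adj:g}",
                stacklevel=3)
            p = adj if p == 0.0 else 1.0 - adj
        return p

    baselines = {}
    for name, mask in submodel_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != y.shape:
            raise ValidationError(f"mask for {name!r} has wrong length")
        if not mask.any():
            raise ValidationError(f"submodel {name!r} has an empty training mask")
        baselines[name] = rate(y[mask], name)
    return CompositeContext(submodel_baselines=baselines,
                            overall_baseline=rate(y, "overall"))


def bin_calibration(
    risks: Sequence[float],
    observed: Sequence[int],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Equal-count calibration bins ordered by predicted risk.

    Pairs are sorted ascending by predicted probability and split into
    ``n_bins`` bins of floor(n / n_bins), with the remainder going to
    the final bin (221 pairs -> nine bins of 22 and a last bin of 23).
    Returns per-bin size, mean predicted probability and observed
    high-impact proportion.
    """
    risks = np.asarray(risks, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = risks.size
    if observed.size != n:
        raise ValidationError("risks and observed must have equal length")
    if n < n_bins:
        raise ValidationError(f"need at least {n_bins} observations, got {n}")
    order = np.argsort(risks, kind="stable")
    base = n // n_bins
    rows = []
    for b in range(n_bins):
        start = b * base
        stop = (b + 1) * base if b < n_bins - 1 else n
        idx = order[start:stop]
        rows.append({
            "bin": b + 1,
            "n": len(idx),
            "mean_predicted": float(risks[idx].mean()),
            "observed_proportion": float(observed[idx].mean()),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RiskSummary:
    sd_logits: float
    p10_logit: float
    p90_logit: float
    p10_prob: float
    p90_prob: float

    @property
    def fold_range(self) -> float:
        return self.p90_prob / self.p10_prob


def risk_summary(risk_logits: Sequence[float]) -> RiskSummary:
    """Spread of risk in logit and probability units.

    Quantiles use linear interpolation between order statistics; the
    fold-range is the ratio of the 90th to the 10th percentile
    probability.
    """
    r = np.asarray(risk_logits, dtype=float)
    if r.size < 10:
        raise ValidationError("need at least 10 risks to summarize")
    p10, p90 = np.percentile(r, [10, 90])
    return RiskSummary(
        sd_logits=float(np.std(r, ddof=1)),
        p10_logit=float(p10), p90_logit=float(p90),
        p10_prob=float(inv_logit(p10)), p90_prob=float(inv_logit(p90)),
    )


# ---------------------------------------------------------------------------
# End-to-end scoring of a census


def score_census(
    census: Census,
    tree: DatedTree,
    coeffs: dict | None = None,
    n_exclude_hosts: int | None = None,
    overrides: Mapping[tuple[str, str], float] | None = None,
    context: CompositeContext | None = None,
) -> pd.DataFrame:
    """Composite risk for every pair of a census, published-coefficient mode.

    Applies the full workflow: closest-native-host divergence per pair
    (conspecific matches excluded from the divergence submodel), the
    documentation filter for the congener submodel (default count: the
    10% rule via :func:`filter_low_documentation_hosts`), availability
    bookkeeping, per-submodel baselines from the observed impacts (or a
    supplied ``context``), and Equation-style logit pooling.
    """
    insects = census.insect_index
    hosts = census.host_index
    host_model = published_host_traits_model(coeffs)
    congener_model = published_congener_model(coeffs)
    guild_models = {g: published_guild_model(g, coeffs)
                    for g in HOST_EVOLUTION_GUILDS}
    excluded = filter_low_documentation_hosts(
        census.hosts, n_exclude=n_exclude_hosts)

    rows = []
    for pair in census.pairs:
        insect = insects[pair.insect_id]
        host = hosts[pair.host_id]
        divergence = np.nan
        conspecific = False
        if insect.native_hosts:
            closest, age = closest_native_host(
                tree, pair.host_id, insect.native_hosts, overrides=overrides)
            conspecific = closest == pair.host_id
            divergence = age
        status = assign_congener_status(insect, host)
        rows.append({
            "insect_id": pair.insect_id,
            "host_id": pair.host_id,
            "high_impact": pair.high_impact,
            "guild": insect.guild,
            "shade_tolerance": host.shade_tolerance,
            "drought_tolerance": host.drought_tolerance,
            "divergence_time_mya": divergence,
            "conspecific": conspecific,
            "host_excluded": pair.host_id in excluded,
            "shared_genus": "yes" if status.shared_genus else "no",
        })
    df = pd.DataFrame(rows)

    avail_host_evo = (
        df["guild"].isin(HOST_EVOLUTION_GUILDS)
        & df["divergence_time_mya"].notna()
        & ~df["conspecific"]
    )
    avail_congener = ~df["host_excluded"]

    df["p_host_traits"] = host_model.predict(df)
    p_evo = np.full(len(df), np.nan)
    for g, model in guild_models.items():
        m = (avail_host_evo & (df["guild"] == g)).to_numpy()
        if m.any():
            p_evo[m] = predict_guild_risk(
                model, df.loc[m, "divergence_time_mya"].to_numpy())
    df["p_host_evolution"] = p_evo
    df["p_insect_evolution"] = np.where(
        avail_congener, congener_model.predict(df), np.nan)

    if context is None:
        context = compute_baselines(
            df["high_impact"].to_numpy(),
            {
                "host_traits": np.ones(len(df), dtype=bool),
                "host_evolution": avail_host_evo.to_numpy(),
                "insect_evolution": avail_congener.to_numpy(),
            },
        )

    logits, probs, n_avail = [], [], []
    for i in range(len(df)):
        preds = {"host_traits": df["p_host_traits"].iat[i]}
        if avail_host_evo.iat[i]:
            preds["host_evolution"] = df["p_host_evolution"].iat[i]
        if avail_congener.iat[i]:
            preds["insect_evolution"] = df["p_insect_evolution"].iat[i]
        risk = composite_risk(preds, context,
                              df["insect_id"].iat[i], df["host_id"].iat[i])
        logits.append(risk.risk_logit)
        probs.append(risk.risk_prob)
        n_avail.append(risk.n_available)
    df["N_available"] = n_avail
    df["risk_logit"] = logits
    df["risk_prob"] = probs
    return df
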