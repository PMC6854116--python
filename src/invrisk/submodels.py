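"""The four submodel families of the invasion-risk workflow.

* insect traits: 12 candidate logistic models on life-history traits
  (none well-supported in the published census);
* host traits: 10 candidates on six tree traits, best supported being
  shade tolerance + drought tolerance;
* host evolutionary history: guild-stratified quadratic-in-log10
  divergence-time logistic models (folivores and sap-feeders only --
  the guilds with at least one high-impact case);
* insect evolutionary history: presence of a native congener on the
  shared host, fitted on hosts passing the documentation filter.

Published coefficients for the three supported submodels ship as a
versioned JSON fixture and drive prediction without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census_io import HostRecord, InsectRecord
from .exceptions import AvailabilityError, FitError, ValidationError
from .glm_core import DesignSpec, FittedModel, Term, fit_logistic, inv_logit

__all__ = [
    "HOST_EVOLUTION_GUILDS",
    "GuildQuadraticModel",
    "CongenerStatus",
    "load_published_coefficients",
    "build_candidate_sets",
    "fit_host_evolution",
    "predict_guild_risk",
    "assign_congener_status",
    "applicable_submodels",
    "published_guild_model",
    "published_host_traits_model",
    "published_congener_model",
]

#: Guilds with at least one high-impact case in the published census;
#: only these have a divergence-time submodel.
HOST_EVOLUTION_GUILDS = ("folivore", "sap_feeder")

SUBMODEL_NAMES = ("host_traits", "host_evolution", "insect_evolution")


def load_published_coefficients() -> dict:
    """Load the packaged published-coefficient fixture."""
    text = (resources.files("invrisk.data") / "published_coefficients.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# Candidate sets


def build_candidate_sets() -> dict[str, list[DesignSpec]]:
    """The published candidate-model lists for multimodel inference.

    Returns design specs keyed by family: 12 insect-trait models
    (including null and global), 10 host-trait models (including null
    and global), and 3 congener models (shared genus / null / shared
    family; no global model because a shared genus implies a shared
    family). Each design carries the published parameter count as
    ``k_nominal`` metadata; the K actually estimated follows from the
    level sets present in the data.
    """
    y = "high_impact"

    def cat(name: str, ref: str) -> Term:
        return Term(name, "categorical", ref)

    def spec(name: str, terms: Sequence[Term], k_nominal: int) -> DesignSpec:
        ds = DesignSpec(y, tuple(terms), name)
        object.__setattr__(ds, "k_nominal", k_nominal)
        return ds

    volt = cat("voltinism", "univoltine")
    repro = cat("reproductive_strategy", "sexual")
    disp = cat("dispersal", "active")
    rng_ = cat("native_range", "asia")
    pest = cat("pest_status", "non_pest")
    guild = cat("guild", "folivore")
    ngen = Term("n_native_host_genera", "continuous")
    cong = cat("congener_present", "no")

    insect = [
        spec("Voltinism", [volt], 2),
        spec("Voltinism + Reproductive Strategy + Dispersal", [volt, repro, disp], 5),
        spec("Reproductive Strategy", [repro], 2),
        spec("Null model", [], 1),
        spec("Congener", [cong], 2),
        spec("Number of Genera", [ngen], 2),
        spec("Pest Status", [pest], 2),
        spec("Dispersal", [disp], 2),
        spec("Native Range", [rng_], 3),
        spec("Guild", [guild], 4),
        spec("Native Range + Pest Status + Number Genera", [rng_, pest, ngen], 5),
        spec("Global model", [volt, repro, disp, rng_, pest, guild, ngen, cong], 11),
    ]

    shade = cat("shade_tolerance", "low")
    drought = cat("drought_tolerance", "none")
    growth = cat("growth_rate", "slow")
    fire = cat("fire_tolerance", "none")
    texture = cat("foliage_texture", "coarse")
    wood = Term("wood_density", "continuous")

    host = [
        spec("Shade tolerance + Drought tolerance", [shade, drought], 6),
        spec("Growth rate", [growth], 3),
        spec("Wood density + Growth rate", [wood, growth], 4),
        spec("Wood density", [wood], 2),
        spec("Null model", [], 1),
        spec("Foliage texture + Growth rate", [texture, growth], 5),
        spec("Foliage texture", [texture], 3),
        spec("Drought tolerance", [drought], 4),
        spec("Global model", [shade, drought, growth, fire, texture, wood], 14),
        spec("Fire tolerance + Drought tolerance", [fire, drought], 7),
    ]

    congener = [
        spec("Shared genus", [cat("shared_genus", "no")], 2),
        spec("Null model", [], 1),
        spec("Shared family", [cat("shared_family", "no")], 2),
    ]

    return {"insect": insect, "host": host, "congener": congener}


# ---------------------------------------------------------------------------
# Host evolutionary history (guild-stratified quadratic)


@dataclass(frozen=True)
class GuildQuadraticModel:
    """Quadratic-in-log10-divergence logistic risk model for one guild.

    risk(t) = inv_logit(b0 + b1 x + b2 x^2) with x = log10(t / 1 my).
    A negative b2 gives a single-peaked risk curve with vertex at
    x* = -b1 / (2 b2), i.e. a most-dangerous divergence time of 10^x* my.
    """

    guild: str
    beta0: float
    beta1: float
    beta2: float
    fit: FittedModel | None = None

    @property
    def vertex_log10(self) -> float:
        if self.beta2 == 0:
            raise FitError("no vertex: quadratic coefficient is zero")
        return -self.beta1 / (2.0 * self.beta2)

    @property
    def peak_divergence_mya(self) -> float:
        return float(10.0 ** self.vertex_log10)

    @property
    def peak_probability(self) -> float:
        return predict_guild_risk(self, self.peak_divergence_mya)


def quadratic_design(response: str = "high_impact") -> DesignSpec:
    """high_impact ~ log10(divergence) + [log10(divergence)]^2."""
    # the squared term reads the same column; give it an aliased name
    return DesignSpec(
        response,
        (Term("divergence_time_mya", "log10"),
         Term("divergence_sq", "sq_log10")),
        "Log10(DivergeTime) + Log10(DivergeTime)^2",
    )


def fit_host_evolution(pairs: pd.DataFrame, guild: str) -> GuildQuadraticModel:
    """Fit the divergence-time quadratic for one feeding guild.

    ``pairs`` needs columns guild, divergence_time_mya and high_impact.
    Guilds with no high-impact case (wood borers, root feeders, gall
    makers in the published census) are refused: the response is
    single-class and the curve cannot be estimated.
    """
    if guild not in HOST_EVOLUTION_GUILDS:
        raise FitError(
            f"no divergence-time model for guild {guild!r}: only "
            f"{HOST_EVOLUTION_GUILDS} have high-impact cases")
    sub = pairs.loc[pairs["guild"] == guild].copy()
    if len(sub) == 0:
        raise FitError(f"no pairs for guild {guild!r}")
    if sub["high_impact"].nunique() < 2:
        raise FitError(
            f"guild {guild!r} has a single-class response "
            f"({int(sub['high_impact'].iloc[0])} only): refusing to fit")
    sub["divergence_sq"] = sub["divergence_time_mya"]
    model = fit_logistic(quadratic_design(), sub)
    b = model.coefficients
    return GuildQuadraticModel(guild=guild, beta0=b[0], beta1=b[1], beta2=b[2],
                               fit=model)


def predict_guild_risk(model: GuildQuadraticModel, divergence_mya) -> float:
    """Probability of high impact at a given divergence time (my)."""
    t = np.asarray(divergence_mya, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("divergence time must be positive")
    x = np.log10(t)
    return inv_logit(model.beta0 + model.beta1 * x + model.beta2 * x**2)


# ---------------------------------------------------------------------------
# Insect evolutionary history (congener/family relatedness)


@dataclass(frozen=True)
class CongenerStatus:
    insect_id: str
    host_id: str
    relation: str  # shared_genus | shared_family_only | none

    @property
    def shared_genus(self) -> bool:
        return self.relation == "shared_genus"

    @property
    def shared_family(self) -> bool:
        return self.relation in ("shared_genus", "shared_family_only")


def assign_congener_status(insect: InsectRecord, host: HostRecord) -> CongenerStatus:
    """Taxonomic relatedness of an invader to the host's native fauna.

    shared_genus if any native insect genus documented on the host
    equals the invader's genus; shared_family_only if only the family
    matches; none otherwise.
    """
    relation = "none"
    for genus, family in host.native_insect_genera:
        if not family:
            raise ValidationError(
                f"host {host.species_id!r}: native genus {genus!r} lacks a "
                "family label")
        if genus == insect.genus:
            relation = "shared_genus"
            break
        if family == insect.family:
            relation = "shared_family_only"
    return CongenerStatus(insect.species_id, host.species_id, relation)


# ---------------------------------------------------------------------------
# Availability


@dataclass(frozen=True)
class AvailabilityContext:
    """What each submodel can see: guild models fitted, hosts excluded
    from the congener analysis, pairs lacking divergence data."""

    guild_models: tuple[str, ...] = HOST_EVOLUTION_GUILDS
    excluded_hosts: frozenset[str] = frozenset()
    pairs_without_divergence: frozenset[tuple[str, str]] = frozenset()


def applicable_submodels(
    pair: Mapping[str, str],
    context: AvailabilityContext,
    guild: str,
) -> tuple[str, ...]:
    """Subset of submodels yielding a prediction for one pair (N in 1..3).

    Host traits always predict. The divergence-time model requires a
    guild with a fitted curve and divergence data for the pair. The
    congener model requires the host to have survived the documentation
    filter.
    """
    key = (pair["insect_id"], pair["host_id"])
    out = ["host_traits"]
    if guild in context.guild_models and key not in context.pairs_without_divergence:
        out.append("host_evolution")
    if pair["host_id"] not in context.excluded_hosts:
        out.append("insect_evolution")
    if not out:
        raise AvailabilityError(f"no submodel available for pair {key}")
    return tuple(out)


# ---------------------------------------------------------------------------
# Published-coefficient prediction modes


def published_guild_model(guild: str, coeffs: dict | None = None) -> GuildQuadraticModel:
    coeffs = coeffs or load_published_coefficients()
    try:
        c = coeffs["host_evolution"][guild]
    except KeyError:
        raise FitError(
            f"no published divergence-time coefficients for guild {guild!r}") from None
    return GuildQuadraticModel(
        guild=guild, beta0=c["intercept"], beta1=c["log10_divergence"],
        beta2=c["log10_divergence_sq"])


def published_host_traits_model(coeffs: dict | None = None) -> FittedModel:
    """Shade + drought logistic model assembled from published values."""
    coeffs = coeffs or load_published_coefficients()
    c = coeffs["host_traits"]
    shade_levels = ("low", "moderate", "high")
    drought_levels = ("none", "low", "moderate", "high")
    columns = ["intercept"] + \
        [f"shade_tolerance.{l}" for l in shade_levels[1:]] + \
        [f"drought_tolerance.{l}" for l in drought_levels[1:]]
    beta = [c["intercept"]] + \
        [c["shade_tolerance"][l] for l in shade_levels[1:]] + \
        [c["drought_tolerance"][l] for l in drought_levels[1:]]
    se = [c["se"]["intercept"]] + \
        [c["se"][f"shade_tolerance.{l}"] for l in shade_levels[1:]] + \
        [c["se"][f"drought_tolerance.{l}"] for l in drought_levels[1:]]
    design = DesignSpec(
        "high_impact",
        (Term("shade_tolerance", "categorical", "low"),
         Term("drought_tolerance", "categorical", "none")),
        "Shade tolerance + Drought tolerance")
    return FittedModel(
        design=design, columns=tuple(columns), coefficients=tuple(beta),
        standard_errors=tuple(se), loglik=np.nan, n=int(c["n"]),
        converged=True, separation_flag=False,
        term_levels={"shade_tolerance": shade_levels,
                     "drought_tolerance": drought_levels})


def published_congener_model(coeffs: dict | None = None) -> FittedModel:
    coeffs = coeffs or load_published_coefficients()
    c = coeffs["insect_evolution"]
    design = DesignSpec(
        "high_impact", (Term("shared_genus", "categorical", "no"),),
        "Shared genus")
    return FittedModel(
        design=design, columns=("intercept", "shared_genus.yes"),
        coefficients=(c["intercept"], c["shared_genus"]),
        standard_errors=(c["se"]["intercept"], c["se"]["shared_genus"]),
        loglik=np.nan, n=int(c["n"]), converged=True, separation_flag=False,
        term_levels={"shared_genus": ("no", "yes")})


def host_trait_probability_grid(coeffs: dict | None = None) -> pd.DataFrame:
    """Predicted probability over the full shade x drought grid."""
    model = published_host_traits_model(coeffs)
    rows = [
        {"shade_tolerance": s, "drought_tolerance": d}
        for s in ("low", "moderate", "high")
        for d in ("none", "low", "moderate", "high")
    ]
    grid = pd.DataFrame(rows)
    grid["probability"] = model.predict(grid)
    return grid
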