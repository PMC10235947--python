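"""Synthetic reproductive-record and meta-dataset generators.

Every pipeline stage is testable without external downloads: these
generators produce individual-level records and multi-group datasets with
known ground truth, emulating the *structure* of a cross-cultural /
cross-species skew compilation — many human populations with marriage and
subsistence labels, several dozen nonhuman mammal species with mating
system labels, heterogeneous group sizes and exposures, over-dispersed
offspring counts.  Configured truths are arbitrary and always returned
alongside the data; no real population's values are imitated.

The alternative-hypothesis generator is gamma-Poisson: individual
reproductive rates are Gamma(shape) distributed and offspring are Poisson
around rate x exposure.  This family nests the multinomial null (shape ->
infinity) and, because the null standardization removes the Poisson term,
has expected multinomial index M ~= 1/shape, independent of the mean rate
and of group size — which is what makes it a clean test bed for the
index's invariance claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import validate_metadata, validate_records
from .skew import compute_M_values, signed_sqrt

logger = logging.getLogger("repskew")

__all__ = [
    "ClassSpec",
    "SyntheticSpec",
    "gen_null_records",
    "gen_skewed_records",
    "gen_meta_dataset",
    "default_study_spec",
    "shape_for_mstar",
]


def _exposures(n: int, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "uniform":
        return np.ones(n)
    if model == "age_spread":
        # age at census for completed-fertility style data
        return rng.uniform(15.0, 75.0, size=n)
    raise ValueError(f"unknown exposure_model {model!r}")


def gen_null_records(
    n: int, K_or_rate, exposure_model: str = "uniform", seed: int = 0,
    group_id: str = "G0", sex: str = "female",
) -> pd.DataFrame:
    """Records drawn from the exposure-weighted multinomial null itself.

    Offspring are allocated multinomially with probabilities proportional
    to exposure, so ground truth is M = 0 in expectation.  ``K_or_rate``
    is either an integer total offspring K or a float per-capita rate
    (then K ~ Poisson(n x rate)).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    exposure = _exposures(n, exposure_model, rng)
    if isinstance(K_or_rate, (int, np.integer)):
        K = int(K_or_rate)
    else:
        K = int(rng.poisson(n * float(K_or_rate)))
    q = exposure / exposure.sum()
    rs = rng.multinomial(K, q)
    df = pd.DataFrame({
        "individual_id": [f"{group_id}_{sex[0]}{i}" for i in range(n)],
        "group_id": group_id, "sex": sex, "rs": rs, "exposure": exposure,
    })
    return validate_records(df)


def gen_skewed_records(
    n: int, mean_rs: float, gamma_shape: float, sex: str = "male", seed: int = 0,
    exposure_model: str = "uniform", group_id: str = "G0",
) -> pd.DataFrame:
    """Gamma-Poisson over-dispersed records with known true skew.

    Individual rates are Gamma(shape, scaled to mean ``mean_rs``); counts
    are Poisson(rate x relative exposure).  Smaller shape means larger
    true skew (expected M ~= 1/shape); shape -> infinity collapses to the
    null.
    """
    if gamma_shape <= 0:
        raise ValueError(f"gamma_shape must be > 0, got {gamma_shape}")
    rng = np.random.default_rng(seed)
    exposure = _exposures(n, exposure_model, rng)
    rates = rng.gamma(gamma_shape, scale=mean_rs / gamma_shape, size=n)
    rs = rng.poisson(rates * exposure / exposure.mean())
    df = pd.DataFrame({
        "individual_id": [f"{group_id}_{sex[0]}{i}" for i in range(n)],
        "group_id": group_id, "sex": sex, "rs": rs, "exposure": exposure,
    })
    return validate_records(df)


def shape_for_mstar(mstar: float, floor: float = 1e-3) -> float:
    """Gamma shape whose expected index matches a target M* (> 0).

    Inverts the gamma-Poisson mapping E[M] ~= 1/shape; targets at or below
    ``floor`` on the M scale map to an effectively null shape of 1e6.
    """
    M = mstar * abs(mstar)
    if M <= floor:
        return 1e6
    return 1.0 / M


@dataclass(frozen=True)
class ClassSpec:
    """One class of groups with its true mean M* per sex and metadata template."""

    label: str
    n_groups: int
    mstar_male: float
    mstar_female: float
    taxon: str = "human"
    mating_system: str | None = None
    marriage_system: str | None = None
    subsistence: str | None = None
    is_primate: bool = False


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint for a multi-group meta-dataset with known truths.

    ``mode="direct"`` draws group-level M* values around the class means
    with SD ``residual_sd``; ``mode="records"`` realizes each group as
    gamma-Poisson individual records (shape inverted from the class mean)
    and runs the index on them, so between-group spread comes from
    sampling alone.  ``n_polygyny_subset`` human groups additionally get a
    continuous percent-female-polygyny covariate.
    """

    classes: tuple[ClassSpec, ...]
    residual_sd: float = 0.3
    n_range: tuple[int, int] = (50, 400)
    mean_fertility: float = 2.0
    exposure_model: str = "uniform"
    mode: str = "direct"
    n_polygyny_subset: int = 0
    pct_high_quality: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.mean_fertility <= 0:
            raise ValueError("mean_fertility must be > 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def gen_meta_dataset(spec: SyntheticSpec):
    """Generate (skew estimates, metadata, truths) for a synthetic study.

    Returns a per group-and-sex estimates table (columns group_id, sex, M,
    M_star, n, K, source), a validated metadata table, and the configured
    truths ``{class label: {"male": m, "female": f, "sexdiff": m - f}}``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    est_rows, meta_rows = [], []
    truths = {}
    gid = 0
    for cls in spec.classes:
        truths[cls.label] = {
            "male": cls.mstar_male, "female": cls.mstar_female,
            "sexdiff": cls.mstar_male - cls.mstar_female,
        }
        for _ in range(cls.n_groups):
            group_id = f"{cls.label}_{gid:03d}"
            gid += 1
            n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
            for sex, truth in (("male", cls.mstar_male), ("female", cls.mstar_female)):
                if spec.mode == "direct":
                    mstar = truth + rng.normal(0.0, spec.residual_sd)
                    M = mstar * abs(mstar)
                    K = max(int(round(n * spec.mean_fertility)), 1)
                elif spec.mode == "records":
                    recs = gen_skewed_records(
                        n, spec.mean_fertility, shape_for_mstar(truth), sex=sex,
                        seed=int(rng.integers(2**31)),
                        exposure_model=spec.exposure_model, group_id=group_id,
                    )
                    rs = recs["rs"].to_numpy(dtype=float)
                    if rs.sum() < 1:
                        logger.warning("skipping %s %s: no offspring realized", group_id, sex)
                        continue
                    M = compute_M_values(rs, recs["exposure"].to_numpy(), method="analytic")
                    mstar = signed_sqrt(M)
                    K = int(rs.sum())
                else:
                    raise ValueError(f"unknown mode {spec.mode!r}")
                est_rows.append({
                    "group_id": group_id, "sex": sex, "M": M, "M_star": mstar,
                    "n": n, "K": K, "source": "records" if spec.mode == "records" else "converted",
                })
            meta_rows.append({
                "group_id": group_id, "taxon": cls.taxon,
                "species_name": "Homo sapiens" if cls.taxon == "human" else f"sp_{cls.label}",
                "is_primate": cls.taxon == "human" or cls.is_primate,
                "mating_system": cls.mating_system,
                "marriage_system": cls.marriage_system,
                "subsistence": cls.subsistence,
                "pct_female_polygyny": None,
                "high_quality_demography": bool(rng.random() < spec.pct_high_quality),
            })
    estimates = pd.DataFrame(est_rows)
    metadata = pd.DataFrame(meta_rows)
    if spec.n_polygyny_subset:
        human_ids = metadata.loc[metadata["taxon"] == "human", "group_id"]
        take = human_ids.sample(
            n=min(spec.n_polygyny_subset, len(human_ids)),
            random_state=int(rng.integers(2**31)),
        )
        pct = rng.uniform(0.0, 50.0, size=len(take))
        metadata.loc[metadata["group_id"].isin(take), "pct_female_polygyny"] = pct
    metadata = validate_metadata(metadata)
    logger.info("synthesized %d groups in %d classes (mode=%s, seed=%d)",
                len(metadata), len(spec.classes), spec.mode, spec.seed)
    return estimates, metadata, truths


# Joint marriage-by-subsistence counts used for the default human layout
# (rows: subsistence; columns: normative monogamy / polygyny tolerated /
# normative polygyny).  These mirror the margins of a typical comparative
# sample: marriage systems 43/33/14 across 90 populations.
HUMAN_LAYOUT = {
    "foraging": (10, 13, 2),
    "horticulture": (7, 14, 3),
    "agropastoralism": (6, 2, 8),
    "agriculture": (11, 4, 1),
    "market": (9, 0, 0),
}

_MARRIAGE_ORDER = ("normative_monogamy", "polygyny_tolerated", "normative_polygyny")


def default_study_spec(seed: int = 0, mode: str = "direct") -> SyntheticSpec:
    """A study-shaped synthetic blueprint: 90 human populations + 49 species.

    Humans are laid out over the joint marriage-by-subsistence table in
    :data:`HUMAN_LAYOUT`; nonhuman mammals split 8 monogamous / 41
    polygynous with 12 primates among them.  The class-level true M*
    values are arbitrary but ordered like the broad comparative pattern
    (high male skew and large sex differences in polygynous nonhumans;
    high, nearly sex-equal skew in monogamous nonhumans; modest, nearly
    sex-equal skew in humans).
    """
    classes = []
    for subsistence, counts in HUMAN_LAYOUT.items():
        for marriage, n in zip(_MARRIAGE_ORDER, counts):
            if n == 0:
                continue
            polyg = marriage == "normative_polygyny"
            classes.append(ClassSpec(
                label=f"h_{subsistence[:4]}_{marriage.split('_')[1][:4]}",
                n_groups=n,
                mstar_male=0.55 if polyg else 0.45,
                mstar_female=0.35 if polyg else 0.40,
                taxon="human", marriage_system=marriage, subsistence=subsistence,
            ))
    classes += [
        ClassSpec("nh_monog", 5, 1.30, 1.20, taxon="nonhuman_mammal",
                  mating_system="monogamous"),
        ClassSpec("nh_monog_primate", 3, 1.25, 1.15, taxon="nonhuman_mammal",
                  mating_system="monogamous", is_primate=True),
        ClassSpec("nh_polyg", 32, 1.10, 0.35, taxon="nonhuman_mammal",
                  mating_system="polygynous"),
        ClassSpec("nh_polyg_primate", 9, 1.05, 0.40, taxon="nonhuman_mammal",
                  mating_system="polygynous", is_primate=True),
    ]
    return SyntheticSpec(
        classes=tuple(classes), residual_sd=0.25, n_range=(50, 400),
        n_polygyny_subset=19, seed=seed, mode=mode,
    )
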