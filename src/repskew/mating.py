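"""Generalized polygyny-threshold mating-market model.

Males hold two kinds of reproductive resources: rival resources R (food,
land, time — divided among a male's wives) and nonrival resources G
(e.g. "good genes" — conferred on all offspring without division).  A
female married to male i alongside k_i − 1 cowives recruits offspring in
expectation proportional to the Cobb-Douglas form

    w = (R_i / k_i)^mu * G_i^(1 - mu),

where mu is the fitness elasticity of rival resources and the nonrival
elasticity gamma = 1 − mu enforces constant returns to scale.  Two
mate-matching rules are compared:

* ``ideal_free`` — free female choice with a male demand side: iterated
  best response in which each female moves to the willing male that
  maximizes her own fitness, until no female (and no male) would prefer
  to change partners — a bilaterally Nash (ideal-free) equilibrium.
  Male demand binds through a polygyny entry cost proportional to his
  own recruitment, so high rival-resource importance (where a cowife
  nearly halves everyone's output) makes every male refuse a second
  wife and monogamy emerges without any norm;
* ``imposed_monogamy`` — a social norm bars females from joining an
  already-paired male, yielding universal monogamy regardless of
  resources.

Resource inequality is measured by the Gini coefficient; resources are
drawn lognormal, for which the Gini has the closed form
2·Phi(sigma/sqrt(2)) − 1 and can therefore be targeted exactly.  Sweeps
over (Gini of R) × mu map each matching rule to polygyny frequency and
to male/female reproductive skew via the multinomial index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import ValidationError
from .skew import compute_M_values

logger = logging.getLogger("repskew")

__all__ = [
    "MatingMarketConfig",
    "MatchingState",
    "gini",
    "lognormal_sigma_for_gini",
    "sample_resources",
    "female_fitness",
    "male_accepts",
    "match_ideal_free",
    "match_imposed_monogamy",
    "is_bilaterally_stable",
    "enumerate_stable_assignments",
    "polygyny_metrics",
    "simulate_reproduction",
    "sweep",
]

UNMATCHED = -1
_TOL = 1e-12


@dataclass(frozen=True)
class MatingMarketConfig:
    """Parameters of one mating market.

    ``gini_R`` is the target Gini of rival resources, ``gini_G`` of
    nonrival resources (held at 0.12 by default), ``mu`` the rival-resource
    fitness elasticity (gamma = 1 − mu is implied).  ``male_cost`` is the
    one-time mating-investment cost of keeping a polygynous household,
    expressed as a fraction of the male's single-wife recruitment; the
    default 0.23 places the demand-side monogamy threshold at mu ~ 0.7.
    """

    n_males: int = 200
    n_females: int | None = None
    gini_R: float = 0.3
    gini_G: float = 0.12
    mu: float = 0.5
    mating_rule: str = "ideal_free"
    male_cost: float = 0.23
    fertility_scale: float = 2.0
    offspring_mode: str = "poisson"  # or "expected"
    replicates: int = 20
    max_sweeps: int = 500
    seed: int = 0

    @property
    def gamma(self) -> float:
        """Nonrival elasticity, 1 − mu (constant returns to scale)."""
        return 1.0 - self.mu

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError(f"mu must lie in [0, 1], got {self.mu}")
        if not (0.0 <= self.gini_R < 1.0) or not (0.0 <= self.gini_G < 1.0):
            raise ValidationError("resource Gini targets must lie in [0, 1)")
        if self.mating_rule not in ("ideal_free", "imposed_monogamy"):
            raise ValidationError(f"unknown mating_rule {self.mating_rule!r}")
        if self.male_cost < 0:
            raise ValidationError("male_cost must be >= 0")
        if self.n_females is not None and self.n_females != self.n_males:
            logger.info("unequal market: %d males, %d females", self.n_males, self.n_females)

    @property
    def n_f(self) -> int:
        return self.n_males if self.n_females is None else self.n_females


@dataclass
class MatchingState:
    """Equilibrium (or terminal) assignment of females to males.

    ``husband[f]`` is the male index of female f (−1 if unmatched);
    ``wife_count[m]`` the number of wives of male m.  ``converged`` is
    False when best-response iteration hit the sweep cap without reaching
    a fixed point.
    """

    husband: np.ndarray
    wife_count: np.ndarray
    R: np.ndarray
    G: np.ndarray
    mu: float
    male_cost: float
    rule: str
    converged: bool = True
    n_sweeps: int = 0

    @property
    def per_wife_share(self) -> np.ndarray:
        """Rival-resource share R_i / k_i per male (NaN for wifeless males)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.wife_count > 0, self.R / self.wife_count, np.nan)


# ---------------------------------------------------------------------------
# Inequality primitives
# ---------------------------------------------------------------------------


def gini(x) -> float:
    """Population Gini coefficient, sum_{ij} |x_i − x_j| / (2 n^2 mean).

    0 for an equal distribution, →1 as a single individual holds all
    shares; scale-invariant.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2:
        raise ValidationError("gini needs at least 2 values")
    if np.any(x < 0):
        raise ValidationError("gini requires non-negative values")
    total = x.sum()
    if total <= 0:
        raise ValidationError("gini undefined for an all-zero vector")
    # sorted-rank identity for the pairwise-difference sum
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def lognormal_sigma_for_gini(target_gini: float) -> float:
    """Lognormal sigma whose population Gini is ``target_gini``.

    Inverts G = 2·Phi(sigma/sqrt(2)) − 1.
    """
    if not (0.0 <= target_gini <= 0.95):
        raise ValidationError(f"target Gini must lie in [0, 0.95], got {target_gini}")
    return float(np.sqrt(2.0) * norm.ppf((target_gini + 1.0) / 2.0))


def sample_resources(n: int, target_gini: float, rng: np.random.Generator | int = 0) -> np.ndarray:
    """Lognormal resource draws with the requested population Gini, mean 1."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sigma = lognormal_sigma_for_gini(target_gini)
    if sigma == 0.0:
        return np.ones(n)
    x = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
    return x / x.mean()


def female_fitness(R_i, k_i, G_i, mu: float):
    """Expected offspring of a wife of male i with k_i wives in total.

    w = (R_i/k_i)^mu · G_i^(1−mu).  Female inputs (gestation, lactation,
    care) are uniform across individuals, so w varies only through the
    husband's per-wife rival share and his nonrival holdings.
    """
    k = np.asarray(k_i, dtype=float)
    if np.any(k < 1):
        raise ValidationError("k_i counts the wife herself and must be >= 1")
    R = np.asarray(R_i, dtype=float)
    G = np.asarray(G_i, dtype=float)
    out = (R / k) ** mu * G ** (1.0 - mu)
    return float(out) if out.ndim == 0 else out


def _male_total(R, G, k, mu, cost):
    """Male expected recruitment with k wives, net of linear mating cost.

    W(k) = q·(k^(1−mu) − cost·1{k ≥ 2}) with q = R^mu G^(1−mu): keeping a
    polygynous household carries a one-time mating-investment cost, a
    fraction ``cost`` of the male's single-wife recruitment, so whether he
    enters polygyny at all depends only on mu (through the marginal
    recruitment of a second wife) and not on how rich he is.
    """
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        base = np.where(k > 0, k ** (1.0 - mu), 0.0)  # wifeless males recruit nothing
    return R**mu * G ** (1.0 - mu) * (base - cost * (k >= 2))


def male_accepts(R, G, k, mu: float, cost: float):
    """Does a male with k wives accept wife k+1?

    Yes iff his total expected recruitment, net of the polygyny entry
    cost, strictly increases.  A first wife is always welcome; a second
    is taken only when the marginal recruitment of a cowife exceeds the
    entry cost (which, being proportional to his own baseline, makes the
    decision depend on mu alone); further wives always add recruitment.
    """
    return _male_total(R, G, np.asarray(k) + 1, mu, cost) - _male_total(R, G, k, mu, cost) > _TOL


def match_imposed_monogamy(
    config: MatingMarketConfig, R: np.ndarray, G: np.ndarray,
    rng: np.random.Generator | int = 0,
) -> MatchingState:
    """Matching under socially imposed monogamy.

    Females choose in randomized order; each picks her fitness-maximizing
    still-unpaired male.  With equal numbers every male ends with exactly
    one wife, so the per-wife rival share is R_i itself.
    """
    if config.mating_rule != "imposed_monogamy":
        raise ValidationError("config.mating_rule must be 'imposed_monogamy'")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_m, n_f = R.size, config.n_f
    husband = np.full(n_f, UNMATCHED, dtype=int)
    available = np.ones(n_m, dtype=bool)
    quality = R**config.mu * G ** (1.0 - config.mu)
    for f in rng.permutation(n_f):
        if not available.any():
            break
        cand = np.where(available, quality, -np.inf)
        m = int(np.argmax(cand))
        husband[f] = m
        available[m] = False
    wife_count = np.bincount(husband[husband >= 0], minlength=n_m)
    return MatchingState(husband, wife_count, R, G, config.mu, config.male_cost,
                         "imposed_monogamy")


def match_ideal_free(
    config: MatingMarketConfig, R: np.ndarray, G: np.ndarray,
    rng: np.random.Generator | int = 0,
) -> MatchingState:
    """Bilateral-Nash matching by randomized sequential best response.

    In each sweep, every female (in randomized order) moves to the willing
    male that maximizes her prospective fitness — computed with his wife
    count incremented by her arrival — if that strictly beats her current
    fitness (ties favor the incumbent, then the lowest male index).  Males
    accept an additional wife only when their net recruitment increases.
    Sweeps repeat until a full pass produces no move (a state in which no
    female can gain by unilaterally switching to any willing male) or the
    sweep cap is hit, in which case the state is flagged unconverged.
    """
    if config.mating_rule != "ideal_free":
        raise ValidationError("config.mating_rule must be 'ideal_free'")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_m, n_f = R.size, config.n_f
    mu, cost = config.mu, config.male_cost
    quality = R**mu * G ** (1.0 - mu)  # w at share denominator 1
    # entry decision is resource-independent: all males share one threshold
    takes_second = bool(2.0 ** (1.0 - mu) - 1.0 - cost > _TOL)
    husband = np.full(n_f, UNMATCHED, dtype=int)
    k = np.zeros(n_m, dtype=int)
    converged = False
    sweeps = 0
    for sweeps in range(1, config.max_sweeps + 1):
        moved = False
        for f in rng.permutation(n_f):
            cur = husband[f]
            w_cur = quality[cur] * k[cur] ** (-mu) if cur != UNMATCHED else 0.0
            # prospective fitness at every other male, if he is willing
            w_new = quality * (k + 1.0) ** (-mu)
            willing = (k == 0) | (k >= 2) if not takes_second else np.ones(n_m, bool)
            if cur != UNMATCHED:
                willing = willing.copy()
                willing[cur] = False
            w_new = np.where(willing, w_new, -np.inf)
            best = int(np.argmax(w_new))
            if w_new[best] > w_cur + _TOL:
                if cur != UNMATCHED:
                    k[cur] -= 1
                husband[f] = best
                k[best] += 1
                moved = True
        if not moved:
            converged = True
            break
    if not converged:
        logger.warning("ideal-free matching hit the sweep cap (%d) without converging",
                       config.max_sweeps)
    return MatchingState(husband, k, R, G, mu, cost, "ideal_free",
                         converged=converged, n_sweeps=sweeps)


def is_bilaterally_stable(state: MatchingState) -> bool:
    """Nash certificate: no profitable unilateral deviation exists.

    Checks every (female, male) pair — no female can strictly increase her
    fitness by switching to a male who would accept her — and the male
    side: no male prefers to shed a wife (his marginal wife still pays for
    herself net of cost).
    """
    R, G, mu, cost = state.R, state.G, state.mu, state.male_cost
    k = state.wife_count
    quality = R**mu * G ** (1.0 - mu)
    # male side: no male prefers to shed his marginal wife
    held = k > 0
    if np.any(_male_total(R[held], G[held], k[held], mu, cost)
              < _male_total(R[held], G[held], k[held] - 1, mu, cost) - _TOL):
        return False
    base_willing = np.asarray(male_accepts(R, G, k, mu, cost))
    for f in range(state.husband.size):
        cur = state.husband[f]
        w_cur = quality[cur] * k[cur] ** (-mu) if cur != UNMATCHED else 0.0
        w_new = quality * (k + 1.0) ** (-mu)
        willing = base_willing
        if cur != UNMATCHED:
            willing = willing.copy()
            willing[cur] = False
        if np.any(w_new[willing] > w_cur + 1e-9):
            return False
    return True


def enumerate_stable_assignments(
    R: np.ndarray, G: np.ndarray, mu: float, cost: float, n_females: int
) -> list[np.ndarray]:
    """Brute-force bilateral-stability oracle for tiny markets.

    Enumerates every assignment of females to males (or to no one) and
    returns those in which no female has a profitable deviation to a
    willing male and no male regrets his marginal wife.  Only feasible for
    a handful of individuals; used to certify the best-response search.
    """
    n_m = R.size
    if (n_m + 1) ** n_females > 100_000:
        raise ValidationError("enumeration oracle is for tiny markets only")
    R = [float(v) for v in R]
    G = [float(v) for v in G]
    tol = 1e-9

    def male_total(m: int, k: int) -> float:
        if k == 0:
            return 0.0
        return R[m] ** mu * G[m] ** (1.0 - mu) * (k ** (1.0 - mu) - cost * (k >= 2))

    def wife_fitness(m: int, k: int) -> float:
        return (R[m] / k) ** mu * G[m] ** (1.0 - mu)

    stable = []
    for assign in itertools.product(range(-1, n_m), repeat=n_females):
        k = [0] * n_m
        for m in assign:
            if m >= 0:
                k[m] += 1
        ok = True
        for m in range(n_m):  # no male regrets his marginal wife
            if k[m] >= 1 and male_total(m, k[m]) < male_total(m, k[m] - 1) - tol:
                ok = False
                break
        if ok:
            for f in range(n_females):  # no female has a profitable deviation
                cur = assign[f]
                w_cur = wife_fitness(cur, k[cur]) if cur >= 0 else 0.0
                for m in range(n_m):
                    if m == cur:
                        continue
                    willing = male_total(m, k[m] + 1) > male_total(m, k[m]) + tol
                    if willing and wife_fitness(m, k[m] + 1) > w_cur + tol:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            stable.append(np.array(assign, dtype=int))
    return stable


def polygyny_metrics(state: MatchingState) -> tuple[float, float]:
    """(% of married men with >1 wife, % of matched women with cowives)."""
    married = state.wife_count > 0
    matched = state.husband >= 0
    if not matched.any():
        raise ValidationError("empty matching: no married pairs")
    pct_men = 100.0 * np.mean(state.wife_count[married] > 1)
    pct_women = 100.0 * np.mean(state.wife_count[state.husband[matched]] > 1)
    return float(pct_men), float(pct_women)


def simulate_reproduction(
    state: MatchingState, config: MatingMarketConfig,
    rng: np.random.Generator | int = 0, group_id: str = "sim",
) -> pd.DataFrame:
    """Realize offspring counts from an equilibrium matching.

    Each matched female's expected offspring is her Cobb-Douglas fitness,
    rescaled so the mean over matched females equals ``fertility_scale``;
    realized counts are Poisson draws around that mean (or the expectation
    itself under ``offspring_mode="expected"``, for deterministic
    surfaces).  A male's reproductive success is the sum over his wives;
    unmatched individuals get rs = 0.  Exposure is 1 for everyone — the
    model abstracts away age structure.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    matched = state.husband >= 0
    lam = np.zeros(state.husband.size)
    if matched.any():
        w = female_fitness(state.R[state.husband[matched]],
                           state.wife_count[state.husband[matched]],
                           state.G[state.husband[matched]], state.mu)
        lam[matched] = w / w.mean() * config.fertility_scale
    if config.offspring_mode == "poisson":
        rs_f = rng.poisson(lam).astype(float)
    elif config.offspring_mode == "expected":
        rs_f = lam
    else:
        raise ValidationError(f"unknown offspring_mode {config.offspring_mode!r}")
    rs_m = np.zeros(state.R.size)
    np.add.at(rs_m, state.husband[matched], rs_f[matched])
    females = pd.DataFrame({
        "individual_id": [f"F{i}" for i in range(rs_f.size)],
        "group_id": group_id, "sex": "female", "rs": rs_f, "exposure": 1.0,
    })
    males = pd.DataFrame({
        "individual_id": [f"M{i}" for i in range(rs_m.size)],
        "group_id": group_id, "sex": "male", "rs": rs_m, "exposure": 1.0,
    })
    return pd.concat([females, males], ignore_index=True)


def _match(config: MatingMarketConfig, R, G, rng) -> MatchingState:
    if config.mating_rule == "ideal_free":
        return match_ideal_free(config, R, G, rng)
    return match_imposed_monogamy(config, R, G, rng)


def sweep(
    gini_R_values, mu_values, rules=("ideal_free", "imposed_monogamy"),
    config: MatingMarketConfig | None = None,
) -> pd.DataFrame:
    """Map a (Gini of R) × mu × rule grid to polygyny and skew surfaces.

    Per cell, ``config.replicates`` independent markets are drawn, matched,
    and reproduced; the table reports replicate means of the polygyny
    percentages and of M_m, M_f and M_m − M_f (computed with the exact
    analytic multinomial null).  Deterministic given ``config.seed``.
    """
    config = config or MatingMarketConfig()
    rows = []
    root = np.random.SeedSequence(config.seed)
    cells = [(r, g, m) for r in rules for g in gini_R_values for m in mu_values]
    seeds = root.spawn(len(cells))
    for (rule, g_R, mu), ss in zip(cells, seeds):
        rng = np.random.default_rng(ss)
        cell_cfg = replace(config, gini_R=float(g_R), mu=float(mu), mating_rule=rule)
        acc = np.zeros(5)
        n_conv = 0
        for _ in range(config.replicates):
            R = sample_resources(cell_cfg.n_males, cell_cfg.gini_R, rng)
            G = sample_resources(cell_cfg.n_males, cell_cfg.gini_G, rng)
            state = _match(cell_cfg, R, G, rng)
            n_conv += state.converged
            pm, pw = polygyny_metrics(state)
            recs = simulate_reproduction(state, cell_cfg, rng)
            M_by_sex = {}
            for sex in ("male", "female"):
                rs = recs.loc[recs["sex"] == sex, "rs"].to_numpy()
                M_by_sex[sex] = compute_M_values(rs, None, method="analytic") \
                    if rs.sum() >= 1 else np.nan
            acc += [pm, pw, M_by_sex["male"], M_by_sex["female"],
                    M_by_sex["male"] - M_by_sex["female"]]
        acc /= config.replicates
        rows.append({
            "gini_R": float(g_R), "mu": float(mu), "mating_rule": rule,
            "pct_polygynous_men": acc[0], "pct_women_with_cowives": acc[1],
            "M_m": acc[2], "M_f": acc[3], "M_sexdiff": acc[4],
            "replicates": config.replicates, "n_converged": n_conv,
        })
    return pd.DataFrame(rows)
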