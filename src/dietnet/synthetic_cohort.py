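"""Seeded synthetic adolescent cohorts with planted rank-correlation structure.

No raw cohort is distributed with the study this package models, so every
downstream stage is exercised on synthetic data: a Gaussian copula couples
14 log-normal food-group marginals through a target Spearman matrix
(converted to a Pearson matrix by the exact copula identity
r = 2 sin(pi * rho_s / 6), with nearest-PSD repair by eigenvalue clipping
when a hand-specified target is not a valid correlation matrix).  Spearman
rank correlation is invariant under the monotone log-normal transform, so
the empirical rank correlations of the generated grams converge to the
target.

Defaults emulate the modelled cohort: four anthropometric strata of sizes
120 / 1155 / 132 / 89 (total 1496), per-group log-medians and spreads
matching published median (IQR) daily grams, all-positive rank-correlation
regimes for the eutrophy- and underweight-like strata and mixed-sign
regimes (e.g. vegetables vs fast food) for the overweight/obesity-like
strata.  Demographic categories are allocated by largest remainder from the
published per-stratum frequencies, then shuffled by seed, so default
cohorts reproduce the printed cross-tabulations exactly.  Demographics are
independent of consumption given the stratum.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import (
    DEFAULT_UNIFORM_CORRECTION_KG,
    BMIReferenceTable,
    lookup_cutoffs,
    make_synthetic_reference_table,
)
from .ffq_ingest import (
    DEFAULT_FREQUENCY_MIDPOINTS,
    FOOD_GROUPS,
    N_GROUPS,
    FoodGroupMap,
    load_default_food_group_map,
)

__all__ = [
    "StratumSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "spearman_to_pearson",
    "simulate_stratum",
    "simulate_cohort",
    "default_simulation_config",
    "planted_target",
    "disaggregate_to_items",
    "write_cohort",
]

#: Published median (q1-q3) daily grams per food group (whole-cohort column);
#: log-normal defaults are derived from these.
_MARGINAL_MEDIAN_IQR: dict[str, tuple[float, float, float]] = {
    "Sugar and sweets": (243.3, 130.2, 436.1),
    "Sweetened beverages": (480.4, 200.0, 915.3),
    "Typical Brazilian dishes": (97.3, 49.3, 239.8),
    "Fast food": (170.4, 80.3, 352.7),
    "Oils": (29.3, 11.5, 51.1),
    "Milk and dairy": (166.4, 70.9, 337.6),
    "Meat": (122.7, 64.0, 236.7),
    "Processed meat products": (11.0, 5.5, 33.0),
    "Rice and cereals": (460.7, 261.8, 730.6),
    "Roots": (24.7, 6.8, 71.8),
    "Beans and legumes": (148.8, 78.0, 286.0),
    "Vegetables": (67.3, 23.1, 161.2),
    "Fruits": (465.7, 218.3, 988.4),
    "Coffee": (106.7, 13.3, 293.3),
}

#: Stratum sizes and per-stratum demographic counts (sex from the cohort
#: cross-tabulation; pubertal stage and SES from the by-status table).
_STRATUM_SIZES = {"underweight": 120, "eutrophy": 1155, "overweight": 132, "obesity": 89}
_SEX_COUNTS = {
    "underweight": {"male": 67, "female": 53},
    "eutrophy": {"male": 471, "female": 684},
    "overweight": {"male": 59, "female": 73},
    "obesity": {"male": 45, "female": 44},
}
_PUBERTAL_COUNTS = {
    "underweight": {"pre_pubertal": 21, "pubertal": 47, "post_pubertal": 51},
    "eutrophy": {"pre_pubertal": 86, "pubertal": 237, "post_pubertal": 824},
    "overweight": {"pre_pubertal": 10, "pubertal": 25, "post_pubertal": 96},
    "obesity": {"pre_pubertal": 8, "pubertal": 16, "post_pubertal": 65},
}
_SES_COUNTS = {
    "underweight": {"good": 54, "poor": 61},
    "eutrophy": {"good": 549, "poor": 564},
    "overweight": {"good": 67, "poor": 62},
    "obesity": {"good": 54, "poor": 32},
}

_PRUDENT = ("Rice and cereals", "Roots", "Beans and legumes", "Vegetables", "Fruits")


@dataclass(frozen=True)
class StratumSpec:
    """Generative parameters for one anthropometric stratum."""

    name: str
    n: int
    target_spearman: np.ndarray  # 14x14 target rank-correlation matrix
    marginal_log_median: np.ndarray  # per-group ln(median grams/day)
    marginal_log_sd: np.ndarray  # per-group log-scale sd

    def __post_init__(self) -> None:
        t = np.asarray(self.target_spearman, dtype=float)
        if t.shape != (N_GROUPS, N_GROUPS):
            raise ValueError(f"target_spearman must be {N_GROUPS}x{N_GROUPS}")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(t), 1.0):
            raise ValueError("target_spearman must have unit diagonal")
        if np.any(np.abs(t) > 1 + 1e-12):
            raise ValueError("target_spearman entries must lie in [-1, 1]")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for arr, label in (
            (self.marginal_log_median, "marginal_log_median"),
            (self.marginal_log_sd, "marginal_log_sd"),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != (N_GROUPS,):
                raise ValueError(f"{label} must have length {N_GROUPS}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{label} must be finite")
        object.__setattr__(self, "target_spearman", t)
        object.__setattr__(
            self, "marginal_log_median", np.asarray(self.marginal_log_median, float)
        )
        object.__setattr__(
            self, "marginal_log_sd", np.asarray(self.marginal_log_sd, float)
        )


@dataclass(frozen=True)
class SimulationConfig:
    strata: tuple[StratumSpec, ...]
    demographic_probs: dict  # stratum -> {"sex": {...}, "pubertal_stage": ..., "ses": ...}
    seed: int = 0
    food_group_names: tuple[str, ...] = FOOD_GROUPS
    age_range: tuple[float, float] = (11.0, 17.9)

    def __post_init__(self) -> None:
        for spec in self.strata:
            probs = self.demographic_probs.get(spec.name)
            if probs is None:
                raise ValueError(f"no demographic probabilities for {spec.name!r}")
            for block, d in probs.items():
                total = sum(d.values())
                if not np.isclose(total, 1.0, atol=1e-9):
                    raise ValueError(
                        f"probabilities for {spec.name}/{block} sum to {total}, not 1"
                    )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "food_group_names": list(self.food_group_names),
            "age_range": list(self.age_range),
            "demographic_probs": self.demographic_probs,
            "strata": [
                {
                    "name": s.name,
                    "n": s.n,
                    "target_spearman": np.asarray(s.target_spearman).tolist(),
                    "marginal_log_median": np.asarray(s.marginal_log_median).tolist(),
                    "marginal_log_sd": np.asarray(s.marginal_log_sd).tolist(),
                }
                for s in self.strata
            ],
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass(frozen=True)
class SyntheticCohort:
    roster: pd.DataFrame
    consumption: pd.DataFrame
    provenance: dict


def spearman_to_pearson(
    target_spearman: np.ndarray,
    psd_tolerance: float = 0.05,
    on_large_repair: str = "warn",
) -> tuple[np.ndarray, float]:
    """Gaussian correlation matrix reproducing a target Spearman matrix.

    Applies the copula identity r = 2 sin(pi * rho_s / 6) elementwise, then
    repairs non-PSD results by clipping negative eigenvalues and rescaling
    the diagonal to 1.  Returns (matrix, max elementwise repair change); a
    change above ``psd_tolerance`` warns, or raises if
    ``on_large_repair='error'``.
    """
    t = np.asarray(target_spearman, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("target must be square")
    if not np.allclose(t, t.T, atol=1e-12):
        raise ValueError("target must be symmetric")
    if not np.allclose(np.diag(t), 1.0):
        raise ValueError("target must have unit diagonal")
    if np.any(np.abs(t) > 1 + 1e-12):
        raise ValueError("target entries must lie in [-1, 1]")

    r = 2.0 * np.sin(np.pi * t / 6.0)
    np.fill_diagonal(r, 1.0)
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() >= -1e-10:
        return r, 0.0

    w, v = np.linalg.eigh(r)
    w_clipped = np.clip(w, 1e-8, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    max_change = float(np.max(np.abs(repaired - r)))
    if max_change > psd_tolerance:
        msg = (
            f"PSD repair changed a correlation entry by {max_change:.4f} "
            f"(tolerance {psd_tolerance})"
        )
        if on_large_repair == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return repaired, max_change


def simulate_stratum(
    spec: StratumSpec,
    seed: int | np.random.SeedSequence | None = None,
    psd_tolerance: float = 0.05,
    on_large_repair: str = "warn",
) -> pd.DataFrame:
    """One stratum's n x 14 daily-gram block from the Gaussian copula."""
    rng = np.random.default_rng(seed)
    r, _ = spearman_to_pearson(
        spec.target_spearman, psd_tolerance=psd_tolerance, on_large_repair=on_large_repair
    )
    if spec.n == 0:
        return pd.DataFrame(np.empty((0, N_GROUPS)), columns=list(FOOD_GROUPS))
    # tiny jitter keeps Cholesky stable after eigenvalue clipping
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(N_GROUPS))
    z = rng.standard_normal((spec.n, N_GROUPS)) @ chol.T
    grams = np.exp(spec.marginal_log_median + spec.marginal_log_sd * z)
    return pd.DataFrame(grams, columns=list(FOOD_GROUPS))


def _largest_remainder(n: int, probs: dict[str, float]) -> dict[str, int]:
    """Integer allocation of n across categories, exact for count-derived probs."""
    cats = list(probs)
    raw = np.array([probs[c] * n for c in cats])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(cats, base.tolist()))


def simulate_cohort(
    config: SimulationConfig,
    reference: BMIReferenceTable | None = None,
    uniform_correction_kg: float = DEFAULT_UNIFORM_CORRECTION_KG,
) -> SyntheticCohort:
    """Full roster + consumption matrix for all configured strata.

    Per stratum: consumption comes from the copula; demographic categories
    are allocated at their exact expected counts and shuffled; age, height
    and BMI are drawn so that the planted anthropometric class is recovered
    when the roster is classified against ``reference`` (a synthetic
    percentile table by default).  All randomness descends from
    ``config.seed`` through named substreams.
    """
    ref = reference if reference is not None else make_synthetic_reference_table()
    root = np.random.SeedSequence(config.seed)
    stratum_seeds = root.spawn(len(config.strata))

    rosters, blocks = [], []
    next_id = 1
    for spec, sseq in zip(config.strata, stratum_seeds):
        cons_seq, demo_seq = sseq.spawn(2)
        block = simulate_stratum(spec, seed=cons_seq)
        rng = np.random.default_rng(demo_seq)
        n = spec.n
        ids = [f"P{j:05d}" for j in range(next_id, next_id + n)]
        next_id += n

        probs = config.demographic_probs[spec.name]
        cats: dict[str, list[str]] = {}
        for blockname in ("sex", "pubertal_stage", "ses"):
            alloc = _largest_remainder(n, probs[blockname])
            labels = [c for c, k in alloc.items() for _ in range(k)]
            rng.shuffle(labels)
            cats[blockname] = labels

        lo, hi = config.age_range
        ages = np.clip(rng.normal(14.3, 1.5, n), lo, hi)
        heights = np.clip(rng.normal(1.62, 0.08, n), 1.30, 1.95)
        bmis, weights = [], []
        for i in range(n):
            p3, p85, p97 = lookup_cutoffs(ref, cats["sex"][i], float(ages[i]))
            if spec.name == "underweight":
                band = (max(p3 - 2.5, 10.0), p3)
            elif spec.name == "eutrophy":
                band = (p3, p85)
            elif spec.name == "overweight":
                band = (p85, p97)
            else:
                band = (p97, p97 + 6.0)
            bmi = rng.uniform(*band)
            bmis.append(bmi)
            weights.append(bmi * heights[i] ** 2 + uniform_correction_kg)

        rosters.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "sex": cats["sex"],
                    "age": np.round(ages, 2),
                    "weight": np.round(weights, 2),
                    "height": np.round(heights, 3),
                    "ses": cats["ses"],
                    "pubertal_stage": cats["pubertal_stage"],
                    "bmi": bmis,
                    "anthro_class": spec.name,
                }
            )
        )
        block.index = pd.Index(ids, name="participant_id")
        blocks.append(block)

    roster = pd.concat(rosters, ignore_index=True)
    consumption = pd.concat(blocks)
    # recompute BMI from the rounded weight/height actually recorded
    roster["bmi"] = (roster["weight"] - uniform_correction_kg) / roster["height"] ** 2
    provenance = {"seed": config.seed, "config_hash": config.content_hash()}
    return SyntheticCohort(roster=roster, consumption=consumption, provenance=provenance)


def _derive_log_params() -> tuple[np.ndarray, np.ndarray]:
    """Log-normal (mu, sigma) per group from published median and IQR.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_{0.75}) with z_{0.75} the
    standard-normal upper quartile (q3/q1 = exp(2 z sigma) for a log-normal).
    """
    from scipy.stats import norm

    z75 = norm.ppf(0.75)
    mu, sd = [], []
    for g in FOOD_GROUPS:
        med, q1, q3 = _MARGINAL_MEDIAN_IQR[g]
        mu.append(np.log(med))
        sd.append(np.log(q3 / q1) / (2 * z75))
    return np.array(mu), np.array(sd)


def planted_target(
    base: float = 0.0,
    pairs: dict[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """14x14 Spearman target: constant off-diagonal plus pair overrides."""
    t = np.full((N_GROUPS, N_GROUPS), float(base))
    np.fill_diagonal(t, 1.0)
    idx = {g: i for i, g in enumerate(FOOD_GROUPS)}
    for (a, b), v in (pairs or {}).items():
        i, j = idx[a], idx[b]
        t[i, j] = t[j, i] = float(v)
    return t


def _three_block_target(
    anti: tuple[str, ...],
    within_prudent: float,
    within_anti: float,
    within_rest: float,
    prudent_anti: float,
    prudent_rest: float,
    anti_rest: float,
) -> np.ndarray:
    """Spearman target over three group blocks.

    Blocks: the prudent groups (cereals/roots/legumes/vegetables/fruits),
    an ``anti`` western subset anticorrelated with them, and the remaining
    groups, with constant correlations within and between blocks.
    """
    def blk(g: str) -> str:
        return "P" if g in _PRUDENT else ("A" if g in anti else "R")

    w = {
        ("P", "P"): within_prudent,
        ("A", "A"): within_anti,
        ("R", "R"): within_rest,
        ("P", "A"): prudent_anti,
        ("P", "R"): prudent_rest,
        ("A", "R"): anti_rest,
    }
    t = np.empty((N_GROUPS, N_GROUPS))
    for i, a in enumerate(FOOD_GROUPS):
        for j, b in enumerate(FOOD_GROUPS):
            if i == j:
                t[i, j] = 1.0
            else:
                key = tuple(sorted((blk(a), blk(b))))
                t[i, j] = w[(key[0], key[1])] if key in w else w[(key[1], key[0])]
    return t


def _default_targets() -> dict[str, np.ndarray]:
    """Per-stratum default Spearman regimes (all positive semidefinite).

    Eutrophy/underweight: uniformly positive rank correlations (underweight
    with coffee largely decoupled).  Overweight/obesity: a western subset
    strongly anticorrelated with the prudent block (e.g. vegetables vs fast
    food) and a weakly correlated remainder, yielding mixed-sign networks
    and bootstrap densities below the eutrophy regime — lowest in obesity.
    """
    eutrophy = planted_target(0.55)
    # one-factor loadings: 0.5 between non-coffee groups, coffee decoupled
    lam = np.full(N_GROUPS, np.sqrt(0.5))
    lam[FOOD_GROUPS.index("Coffee")] = 0.25
    underweight = np.outer(lam, lam)
    np.fill_diagonal(underweight, 1.0)
    overweight = _three_block_target(
        ("Fast food", "Oils"), 0.55, 0.6, 0.4, -0.55, 0.25, 0.1
    )
    obesity = _three_block_target(
        ("Fast food", "Processed meat products", "Milk and dairy", "Coffee"),
        0.6, 0.55, 0.25, -0.55, 0.1, 0.1,
    )
    return {
        "underweight": underweight,
        "eutrophy": eutrophy,
        "overweight": overweight,
        "obesity": obesity,
    }


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """Defaults emulating the modelled cohort's published structure."""
    mu, sd = _derive_log_params()
    targets = _default_targets()
    strata = tuple(
        StratumSpec(
            name=name,
            n=_STRATUM_SIZES[name],
            target_spearman=targets[name],
            marginal_log_median=mu,
            marginal_log_sd=sd,
        )
        for name in ("underweight", "eutrophy", "overweight", "obesity")
    )
    demo = {}
    for name in _STRATUM_SIZES:
        demo[name] = {
            "sex": _normalize(_SEX_COUNTS[name]),
            "pubertal_stage": _normalize(_PUBERTAL_COUNTS[name]),
            "ses": _normalize(_SES_COUNTS[name]),
        }
    return SimulationConfig(strata=strata, demographic_probs=demo, seed=seed)


def _normalize(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def disaggregate_to_items(
    consumption: pd.DataFrame,
    group_map: FoodGroupMap | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Split group daily grams into item-level FFQ responses (round-trip helper).

    For each participant x group with positive grams, a random item of the
    group and a random non-rare frequency category are chosen and the portion
    solved so that the implied item daily grams equal the group grams.  No
    fidelity to real FFQ answer patterns is claimed.
    """
    gm = group_map if group_map is not None else load_default_food_group_map()
    rng = np.random.default_rng(seed)
    nonrare = [c for c in DEFAULT_FREQUENCY_MIDPOINTS if c != "never_rare"]
    rows = []
    for pid, row in consumption.iterrows():
        for group in FOOD_GROUPS:
            grams = float(row[group])
            if grams <= 0:
                continue
            items = gm.items_in_group(group)
            item = int(rng.choice(items))
            cat = str(rng.choice(nonrare))
            occ = DEFAULT_FREQUENCY_MIDPOINTS[cat]
            rows.append(
                {
                    "participant_id": str(pid),
                    "item_id": item,
                    "frequency_category": cat,
                    "times": 1,
                    "portion_grams": grams / occ,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "item_id", "frequency_category", "times", "portion_grams"],
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write roster/consumption CSVs plus a JSON provenance sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    roster_path = out / "roster.csv"
    cons_path = out / "consumption.csv"
    meta_path = out / "cohort_meta.json"
    cohort.roster.to_csv(roster_path, index=False)
    cohort.consumption.to_csv(cons_path, index=True)
    meta_path.write_text(json.dumps(cohort.provenance, indent=2))
    return {
        "roster": str(roster_path),
        "consumption": str(cons_path),
        "metadata": str(meta_path),
    }
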