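"""Synthetic cell patterns and cohorts with tunable immune-cancer colocalization.

Patterns come from a Thomas-type cluster process: Poisson parents scattered
uniformly in the window, Gaussian-dispersed offspring around each parent.
Cancer cells are offspring of "cancer parents".  Immune cells are split by
the colocalization dial ρ ∈ [0, 1]: a fraction ρ of the expected immune
count is attached to the *cancer* parents (shared habitat → colocalized),
the remaining 1−ρ to an independent set of immune-only parents (segregated).
ρ = 1 therefore yields strongly overlapping count surfaces and a high
Morisita-Horn index; ρ = 0 yields segregated ones.  Stromal cells are
uniform background and only matter for tissue filtering.

Cohorts link the per-patient ρ to survival through a proportional-hazards
model: a Weibull baseline, a protective log-hazard β for patients whose ρ
exceeds a generative threshold (a step link, so a cutoff search has a
recoverable ground truth), ordinal effects for grade/node/size, random
censoring uniform on the 10-year window and administrative censoring at 120
months.  One global seed fans out to independent per-patient substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .patterns import SlidePattern
from .survival import ADMIN_CENSOR_MONTHS, SIZE_ORDER, PAM50_LEVELS


@dataclass
class PatternConfig:
    """Parameters of the two-class clustered point pattern.

    Defaults give a ~2000 × 2000 μm field with roughly 4-5 thousand cells —
    a desk-scale section with the same square-grid geometry (8 × 8 polygons
    at the 250 μm default) as a whole tumor section.
    """

    width: float = 2000.0  # μm
    height: float = 2000.0  # μm
    kappa: float = 5e-6  # parents per μm² (≈ 20 parents in the default window)
    mu_cancer: float = 100.0  # mean cancer offspring per parent
    mu_immune: float = 50.0  # mean immune offspring per parent
    sigma: float = 60.0  # μm, Gaussian dispersal
    rho: float = 0.5  # colocalization mix ∈ [0, 1]
    stromal_fraction: float = 0.3  # stromal share of all cells (expectation)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.kappa < 0 or self.mu_cancer < 0 or self.mu_immune < 0:
            raise ValueError("intensities must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.stromal_fraction < 1:
            raise ValueError("stromal_fraction must lie in [0, 1)")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def expected_cancer(self) -> float:
        return self.kappa * self.area * self.mu_cancer

    @property
    def expected_immune(self) -> float:
        return self.kappa * self.area * self.mu_immune


@dataclass
class SurvivalConfig:
    """Proportional-hazards survival generator.

    Hazard h(t) = h0(t)·exp(lp) with a Weibull baseline
    h0(t) = (shape/scale)·(t/scale)^(shape−1) and linear predictor
    lp = β·1[ρ > rho_threshold] + node/size/grade effects.  Follow-up is
    administratively censored at 120 months for most patients — emulating a
    cohort with near-complete 10-year follow-up — while a ``dropout_fraction``
    minority is censored at an independent Uniform(0, 120) time (early loss
    to follow-up).
    """

    shape: float = 1.0  # Weibull shape (1 → exponential)
    scale: float = 1200.0  # months; cohort-average 10-y event fraction ≈ 25%
    beta_high: float = float(np.log(0.5))  # protective effect of colocalization
    rho_threshold: float = 0.5  # generative step in the ρ → hazard link
    beta_node: float = float(np.log(2.0))
    beta_size: float = float(np.log(1.6))  # per ordinal step
    beta_grade: float = float(np.log(1.6))  # per grade step above 1
    dropout_fraction: float = 0.2  # share censored early, Uniform(0, 120)
    censor_horizon: float = ADMIN_CENSOR_MONTHS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.censor_horizon != ADMIN_CENSOR_MONTHS:
            raise ValueError("the administrative horizon is fixed at 120 months")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must lie in [0, 1]")


def _scatter_offspring(
    rng: np.random.Generator,
    parents: np.ndarray,
    counts: np.ndarray,
    sigma: float,
    window: tuple[float, float, float, float],
) -> np.ndarray:
    """Gaussian offspring around parents, reflected back into the window."""
    total = int(counts.sum())
    if total == 0:
        return np.empty((0, 2))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=(total, 2))
    xmin, ymin, xmax, ymax = window
    # reflect at the boundary (repeat in case of large excursions)
    for dim, lo, hi in ((0, xmin, xmax), (1, ymin, ymax)):
        v = pts[:, dim]
        span = hi - lo
        v = np.abs((v - lo) % (2 * span) - span) + lo  # triangle-wave reflection
        # guard exact upper edge from float wrap
        pts[:, dim] = np.clip(v, lo, hi)
    return pts


def simulate_pattern(cfg: PatternConfig, patient_id: str = "sim", section_id: str = "s1") -> SlidePattern:
    """Draw one slide pattern from the Thomas-type colocalization model."""
    rng = np.random.default_rng(cfg.seed)
    window = (0.0, 0.0, cfg.width, cfg.height)
    if cfg.expected_cancer == 0 or cfg.expected_immune == 0:
        warnings.warn("expected count of a cell class is zero")
    n_parents = rng.poisson(cfg.kappa * cfg.area)
    n_parents = max(n_parents, 1)
    cancer_parents = np.column_stack(
        [rng.uniform(0, cfg.width, n_parents), rng.uniform(0, cfg.height, n_parents)]
    )
    # cancer offspring
    cancer_counts = rng.poisson(cfg.mu_cancer, n_parents)
    cancer_pts = _scatter_offspring(rng, cancer_parents, cancer_counts, cfg.sigma, window)
    # immune offspring: share rho on cancer parents, 1-rho on immune-only parents
    coloc_counts = rng.poisson(cfg.rho * cfg.mu_immune, n_parents)
    coloc_pts = _scatter_offspring(rng, cancer_parents, coloc_counts, cfg.sigma, window)
    n_ipar = max(rng.poisson(cfg.kappa * cfg.area), 1)
    immune_parents = np.column_stack(
        [rng.uniform(0, cfg.width, n_ipar), rng.uniform(0, cfg.height, n_ipar)]
    )
    seg_counts = rng.poisson((1 - cfg.rho) * cfg.mu_immune * n_parents / n_ipar, n_ipar)
    seg_pts = _scatter_offspring(rng, immune_parents, seg_counts, cfg.sigma, window)
    immune_pts = np.vstack([coloc_pts, seg_pts])
    # stromal background, uniform
    n_cls = len(cancer_pts) + len(immune_pts)
    f = cfg.stromal_fraction
    n_stromal = rng.poisson(f / (1 - f) * n_cls) if f > 0 else 0
    stromal_pts = np.column_stack(
        [rng.uniform(0, cfg.width, n_stromal), rng.uniform(0, cfg.height, n_stromal)]
    )

    xy = np.vstack([cancer_pts, immune_pts, stromal_pts])
    labels = np.concatenate(
        [
            np.full(len(cancer_pts), "cancer", dtype=object),
            np.full(len(immune_pts), "immune", dtype=object),
            np.full(len(stromal_pts), "stromal_other", dtype=object),
        ]
    )
    return SlidePattern(
        patient_id=patient_id,
        section_id=section_id,
        x=xy[:, 0],
        y=xy[:, 1],
        cell_class=labels,
        window=window,
    )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical covariates with marginals typical of an unselected breast-cancer cohort."""
    grade = rng.choice([1, 2, 3], size=n, p=[0.10, 0.35, 0.55])
    node = rng.choice(["neg", "pos"], size=n, p=[0.47, 0.53])
    size_cat = rng.choice(SIZE_ORDER, size=n, p=[0.36, 0.56, 0.08])
    er = rng.choice(["neg", "pos"], size=n, p=[0.25, 0.75])
    her2 = rng.choice(["not_amplified", "amplified"], size=n, p=[0.87, 0.13])
    pam50 = rng.choice(PAM50_LEVELS, size=n, p=[0.18, 0.11, 0.33, 0.26, 0.12])
    ct = rng.binomial(1, 0.25, size=n)
    rt = rng.binomial(1, 0.6, size=n)
    ht = rng.binomial(1, 0.6, size=n)
    return pd.DataFrame(
        {
            "grade": grade, "node": node, "size_cat": size_cat, "er": er,
            "her2": her2, "pam50": pam50, "ct": ct, "rt": rt, "ht": ht,
        }
    )


def draw_survival(
    rng: np.random.Generator, lp: np.ndarray, surv: SurvivalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Event/censoring times from the Weibull PH model by inversion."""
    n = len(lp)
    u = rng.uniform(size=n)
    t_event = surv.scale * (-np.log(u) / np.exp(lp)) ** (1.0 / surv.shape)
    c = np.full(n, surv.censor_horizon)
    drop = rng.uniform(size=n) < surv.dropout_fraction
    c[drop] = rng.uniform(0.0, surv.censor_horizon, size=int(drop.sum()))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)  # survival times must be positive
    return time, event


def expected_event_fraction(surv: SurvivalConfig, lp: float = 0.0, n_grid: int = 4000) -> float:
    """Analytic P(event) under the Weibull PH model with the mixed censoring.

    With probability 1−d the censoring time is the horizon H, with
    probability d it is Uniform(0, H), so
    P(event) = (1−d)·F(H) + d·∫0H F(t) dt / H, F the Weibull cdf at the
    given linear predictor.  Used to check the generator's calibration.
    """
    h = surv.censor_horizon
    t = np.linspace(0, h, n_grid)
    f = 1.0 - np.exp(-((t / surv.scale) ** surv.shape) * np.exp(lp))
    d = surv.dropout_fraction
    return float((1 - d) * f[-1] + d * np.trapezoid(f, t) / h)


def simulate_cohort(
    n_discovery: int = 486,
    n_validation: int = 516,
    sections_per_patient: int = 3,
    pattern_cfg: PatternConfig | None = None,
    surv: SurvivalConfig | None = None,
    seed: int | None = None,
    rho_values: np.ndarray | None = None,
) -> tuple[list[SlidePattern], pd.DataFrame]:
    """Simulate a two-cohort study: cell tables plus linked clinical records.

    Each patient draws a colocalization level ρ ~ Uniform(0, 1) (or from
    ``rho_values``), receives ``sections_per_patient`` independent sections
    at that ρ, and survival from the PH model in which crossing
    ``surv.rho_threshold`` confers the protective hazard ``exp(beta_high)``.
    One global seed spawns independent per-patient substreams, so any
    patient's pattern is reproducible in isolation.
    """
    if n_discovery < 2 or n_validation < 2:
        raise ValueError("each cohort needs at least 2 patients")
    if sections_per_patient < 1:
        raise ValueError("need at least one section per patient")
    pattern_cfg = pattern_cfg or PatternConfig()
    surv = surv or SurvivalConfig()
    n = n_discovery + n_validation
    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root.spawn(1)[0])
    patient_seqs = root.spawn(n)

    rho = (
        master.uniform(0, 1, size=n)
        if rho_values is None
        else np.asarray(rho_values, dtype=float)
    )
    if len(rho) != n:
        raise ValueError("rho_values must have one entry per patient")
    cov = _draw_covariates(master, n)
    high = (rho > surv.rho_threshold).astype(float)
    size_ord = cov["size_cat"].map({s: i for i, s in enumerate(SIZE_ORDER)}).to_numpy()
    lp = (
        surv.beta_high * high
        + surv.beta_node * (cov["node"] == "pos").to_numpy()
        + surv.beta_size * size_ord
        + surv.beta_grade * (cov["grade"].to_numpy() - 1)
    )
    time, event = draw_survival(master, lp, surv)

    patterns: list[SlidePattern] = []
    rows = []
    for i in range(n):
        pid = f"P{i:04d}"
        cohort = "discovery" if i < n_discovery else "validation"
        prng_seqs = patient_seqs[i].spawn(sections_per_patient)
        for s in range(sections_per_patient):
            sec_seed = int(prng_seqs[s].generate_state(1)[0] % (2**31))
            cfg = replace(pattern_cfg, rho=float(rho[i]), seed=sec_seed)
            patterns.append(simulate_pattern(cfg, patient_id=pid, section_id=f"S{s+1}"))
        rows.append(
            {
                "patient_id": pid,
                "time": float(time[i]),
                "event": int(event[i]),
                **cov.iloc[i].to_dict(),
                "cohort": cohort,
                "true_rho": float(rho[i]),
            }
        )
    clinical = pd.DataFrame(rows)
    return patterns, clinical


def fixture_tables() -> dict:
    """Canned worked examples shared across the test suites.

    Includes the internally consistent printed contingency tables of the
    study population (immune abundance × Morisita group) and the analytic
    quadrat-count fixtures with known index values.
    """
    from .tessellation import QuadratCounts

    return {
        # immune abundance (low/high) x Morisita (high/low), all subtypes
        "ia_morisita_discovery": np.array([[89, 148], [227, 22]]),
        "ia_morisita_validation": np.array([[71, 111], [306, 28]]),
        # death (no/yes) x Morisita (high/low)
        "death_morisita_discovery": np.array([[246, 113], [64, 53]]),
        "death_morisita_her2_validation": np.array([[35, 13], [2, 7]]),
        # ER (neg/pos) x Morisita (high/low), Her2-amplified validation
        "er_morisita_her2_validation": np.array([[14, 14], [23, 6]]),
        # analytic Morisita-Horn fixtures
        "mh_proportional": QuadratCounts.from_arrays(x=[3, 3, 3, 3], y=[3, 3, 3, 3]),
        "mh_disjoint": QuadratCounts.from_arrays(x=[5, 0], y=[0, 7]),
        "mh_five_sevenths": QuadratCounts.from_arrays(x=[1, 2, 3], y=[3, 2, 1]),
        "pearson_example": QuadratCounts.from_arrays(x=[0, 1, 2, 5], y=[1, 0, 3, 4]),
    }
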