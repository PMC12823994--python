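"""Synthetic cohort generator with the statistical structure of large
immunosequencing studies.

The generator is *constructive*: it samples target summary metrics
(S, D, S_k) per subject from covariate-shifted distributions and then builds
a clone table that realises each target exactly, so downstream metric code
can be tested against known ground truth.  It emulates:

* log-normal cross-subject distributions of repertoire size S and
  diversity D, centred on the scale of large population cohorts
  (median S ~ 5x10^5 templates, median D ~ 3x10^5 clonotypes);
* age, sex and CMV-serostatus effects on S and on top-k clone mass
  (clonal expansion P_k rising from ~10% at age 20 to ~30% at age 80,
  lower in females, higher in CMV-positive subjects);
* a diversity link D = a*S - b*S_k with dex-scale intrinsic scatter, so
  covariates act on D only through size and clonality (the mediation
  structure the analysis is designed to detect); an alternative
  "lognormal" mode draws (log10 S, log10 D) from a covariate-shifted
  bivariate normal with direct covariate effects on D;
* multinomial sequencing subsampling at a stated depth; and
* paired technical replicates with configurable dex-scale noise on
  log10(D/S), for calibrating the measurement-error estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, FeasibilityError
from .repertoire import CloneTable, SubjectCovariates, compute_metrics

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Feasible metric triples and the exact constructor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricTriple:
    """Target (S, D, S_k) for one repertoire; validated for realisability.

    Feasibility requires: D >= 1; 1 <= k <= D; every clone holds >= 1
    template (S - S_k >= D - k; S_k >= k); and rank consistency: the
    smallest of the k most abundant clones must be at least as large as the
    largest tail clone, which an as-even-as-possible split achieves iff
    floor(S_k / k) >= ceil((S - S_k) / (D - k)) when D > k.
    """

    S: int
    D: int
    S_k: int
    k: int

    def __post_init__(self) -> None:
        validate_triple(self.S, self.D, self.S_k, self.k)


def validate_triple(S: int, D: int, S_k: int, k: int) -> None:
    """Raise FeasibilityError naming the violated constraint, if any."""
    if D < 1:
        raise FeasibilityError(f"D must be >= 1, got {D}")
    if k < 1:
        raise FeasibilityError(f"k must be >= 1, got {k}")
    if k > D:
        raise FeasibilityError(f"k={k} exceeds D={D}")
    if D > S:
        raise FeasibilityError(f"D={D} > S={S}: each clone needs >= 1 template")
    if S_k < k:
        raise FeasibilityError(f"S_k={S_k} < k={k}: each top clone needs >= 1 template")
    if S - S_k < D - k:
        raise FeasibilityError(
            f"tail mass S-S_k={S - S_k} cannot cover D-k={D - k} tail clones"
        )
    if D == k and S_k != S:
        raise FeasibilityError(f"k=D={k} forces S_k=S but got S_k={S_k}, S={S}")
    if D > k:
        min_top = S_k // k
        max_tail = -((S - S_k) // -(D - k))  # ceil division
        if min_top < max_tail:
            raise FeasibilityError(
                f"rank inversion: floor(S_k/k)={min_top} < ceil((S-S_k)/(D-k))={max_tail}"
            )


def is_feasible(S: int, D: int, S_k: int, k: int) -> bool:
    try:
        validate_triple(S, D, S_k, k)
    except FeasibilityError:
        return False
    return True


def _even_split(total: int, parts: int) -> np.ndarray:
    """Split ``total`` into ``parts`` integers differing by <= 1, descending."""
    q, r = divmod(total, parts)
    return np.concatenate([np.full(r, q + 1, np.int64), np.full(parts - r, q, np.int64)])


def construct_clone_table(
    target: MetricTriple,
    seed: int = 0,
    subject_id: str = "synthetic",
    profile: str = "even",
    geometric_decay: float = 0.995,
) -> CloneTable:
    """Build a clone table whose metrics equal the target exactly.

    The S - S_k tail templates are spread over D - k tail clones as evenly
    as possible; the S_k top templates are spread over the k top clones
    either evenly (``profile="even"``) or with a geometric rank-abundance
    decay (``profile="geometric"``) to create a heavier head.  Any rank
    inversion introduced by the geometric profile is repaired by raising
    deficient top clones to the tail ceiling and removing the excess from
    the largest clones, so the round trip through ``compute_metrics`` is
    exact for either profile.
    """
    if profile not in {"even", "geometric"}:
        raise ValueError(f"unknown profile {profile!r}")
    S, D, S_k, k = target.S, target.D, target.S_k, target.k
    n_tail = D - k
    tail = _even_split(S - S_k, n_tail) if n_tail else np.empty(0, np.int64)
    max_tail = int(tail[0]) if n_tail else 1

    if profile == "even" or k == 1:
        top = _even_split(S_k, k)
    else:
        if not 0.0 < geometric_decay < 1.0:
            raise ValueError("geometric_decay must be in (0, 1)")
        w = geometric_decay ** np.arange(k, dtype=np.float64)
        raw = np.floor(S_k * w / w.sum()).astype(np.int64)
        # largest-remainder apportionment of the leftover templates
        frac = S_k * w / w.sum() - raw
        leftover = S_k - int(raw.sum())
        if leftover:
            raw[np.argsort(-frac, kind="stable")[:leftover]] += 1
        # repair: every top clone must reach the tail ceiling ...
        top = np.maximum(raw, max_tail)
        excess = int(top.sum()) - S_k
        # ... funded by trimming the largest clones (feasibility guarantees
        # S_k >= k * max_tail, so the excess is always absorbable)
        i = 0
        while excess > 0:
            cut = min(excess, int(top[i]) - max_tail)
            top[i] -= cut
            excess -= cut
            i += 1
        top = np.sort(top)[::-1]

    counts = np.concatenate([top, tail])
    width = len(str(D))
    ids = tuple(f"c{i:0{width}d}" for i in range(1, D + 1))
    return CloneTable(subject_id=subject_id, clone_ids=ids, templates=counts)


def project_to_feasible(S: int, D: int, S_k: int, k: int) -> tuple[int, int, int, bool]:
    """Project (S, D, S_k) onto the nearest feasible triple for this k.

    S is kept fixed; S_k is adjusted first, then D.  Returns the projected
    triple and whether any adjustment was made.
    """
    orig = (S, D, S_k)
    S = max(int(S), 1)
    D = int(min(max(D, 1), S))
    S_k = int(S_k)
    if D <= k:
        S_k = S
    else:
        hi = S - (D - k)  # leave one template per tail clone
        lo = max(k, -((k * S) // -D))  # ceil(k*S/D): even-abundance lower bound
        S_k = min(max(S_k, lo), hi)
        guard = 0
        while not is_feasible(S, D, S_k, k) and S_k < hi:
            S_k += 1
            guard += 1
            if guard > k + 2:  # pragma: no cover - lo bound makes this unreachable
                break
        if not is_feasible(S, D, S_k, k):
            # fall back to shrinking D (fewer, larger clones)
            while D > k and not is_feasible(S, D, S_k, k):
                D -= 1
                S_k = min(max(S_k, k), S - (D - k))
            if D == k:
                S_k = S
    changed = (S, D, S_k) != orig
    return S, D, S_k, changed


def random_feasible_triple(rng: np.random.Generator, s_max: int = 200) -> MetricTriple:
    """Draw a uniformly-random-ish feasible triple with S <= s_max."""
    while True:
        S = int(rng.integers(1, s_max + 1))
        D = int(rng.integers(1, S + 1))
        k = int(rng.integers(1, D + 1))
        if D == k:
            return MetricTriple(S=S, D=D, S_k=S, k=k)
        lo, hi = k, S - (D - k)
        S_k = int(rng.integers(lo, hi + 1))
        S_k = project_to_feasible(S, D, S_k, k)[2]
        if is_feasible(S, D, S_k, k):
            return MetricTriple(S=S, D=D, S_k=S_k, k=k)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Generative settings for a synthetic cohort.

    Defaults are calibrated to the scale of large population
    immunosequencing cohorts: median repertoire size ~518,600 templates and
    median diversity ~319,800 clonotypes at the reference age of 50, with
    cross-subject dispersions chosen so the central 95% spans roughly
    0.58 dex in log10 S; clonal expansion P_k rises linearly from 10% at
    age 20 to 30% at age 80, is 3 percentage points lower in females and
    5 points higher in CMV-positive subjects.  Noise scales (dex = base-10
    log units): intrinsic diversity scatter 0.015, per-subject measurement
    noise 0.027, replicate per-measurement noise 0.027/sqrt(2) so replicate
    pair differences in log10(D/S) have sd 0.027.
    """

    n_subjects: int = 1000
    seed: int = 0
    k: int = 1000
    # covariate distributions
    age_min: float = 20.0
    age_max: float = 80.0
    male_fraction: float = 0.472
    cmv_positive_base: float = 0.20      # P(CMV+) at age_min
    cmv_positive_slope: float = 0.006    # per year of age
    cmv_unknown_fraction: float = 0.0
    # repertoire size model: log10 S ~ Normal(mu(age, sex, CMV), sd)
    log10_s_median: float = math.log10(518_618.0)
    log10_s_sd: float = 0.14
    reference_age: float = 50.0
    age_slope_log10_s: float = -0.003    # dex / year
    male_offset_log10_s: float = 0.0
    cmv_offset_log10_s: float = 0.08
    # clonality model: P_k (percent of repertoire in top k clones)
    p_k_at_age20: float = 10.0
    p_k_age_slope: float = 20.0 / 60.0   # percent / year: 10% -> 30% over 20-80
    p_k_female_offset: float = -3.0
    p_k_cmv_offset: float = 5.0
    p_k_noise_sd: float = 5.0
    p_k_floor: float = 0.5
    p_k_ceiling: float = 80.0
    # diversity model
    d_link: str = "linear"               # "linear" or "lognormal"
    link_a: float = 0.825                # D = link_a * S - link_b * S_k ...
    link_b: float = 0.965
    intrinsic_noise_sd: float = 0.015    # dex on log10 D (biological scatter)
    measurement_noise_sd: float = 0.027  # dex on measured log10 D
    # lognormal-mode parameters (direct covariate effects on D)
    log10_d_median: float = math.log10(319_802.0)
    log10_d_sd: float = 0.177
    s_d_correlation: float = 0.7
    age_slope_log10_d: float = -0.003
    male_offset_log10_d: float = -0.05
    cmv_offset_log10_d: float = -0.02
    # sequencing / clone-table shape
    depth: int | None = None             # multinomial subsampling depth
    profile: str = "even"
    geometric_decay: float = 0.995
    replicate_noise_sd: float = 0.027 / math.sqrt(2.0)

    def validate(self) -> None:
        for name in (
            "log10_s_sd", "p_k_noise_sd", "intrinsic_noise_sd",
            "measurement_noise_sd", "log10_d_sd", "replicate_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not -1.0 <= self.s_d_correlation <= 1.0:
            raise ConfigError("s_d_correlation must lie in [-1, 1]")
        if self.depth is not None and self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.d_link not in {"linear", "lognormal"}:
            raise ConfigError(f"d_link must be 'linear' or 'lognormal', got {self.d_link!r}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must lie in [0, 1]")
        if not 0.0 <= self.cmv_unknown_fraction <= 1.0:
            raise ConfigError("cmv_unknown_fraction must lie in [0, 1]")
        if self.age_min <= 0 or self.age_max < self.age_min:
            raise ConfigError("require 0 < age_min <= age_max")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    """Output bundle: clone tables (when materialised), covariates, metrics."""

    clone_tables: list[CloneTable]
    covariates: list[SubjectCovariates]
    metrics: pd.DataFrame  # cohort table: subject_id, covariates, S, D, S_k columns
    n_projected: int = 0
    params: SimulationParams | None = None


def _covariate_draw(params: SimulationParams, rng: np.random.Generator):
    n = params.n_subjects
    age = rng.uniform(params.age_min, params.age_max, n)
    male = rng.random(n) < params.male_fraction
    p_cmv = np.clip(
        params.cmv_positive_base + params.cmv_positive_slope * (age - params.age_min), 0, 1
    )
    cmv_pos = rng.random(n) < p_cmv
    unknown = rng.random(n) < params.cmv_unknown_fraction
    return age, male, cmv_pos, unknown


def simulate_cohort(params: SimulationParams, materialize: bool = True) -> SimulatedCohort:
    """Generate a synthetic cohort; fully reproducible from ``params.seed``.

    Per subject: draw covariates; draw log10 S from the covariate-shifted
    normal; draw a clonality target P_k and convert it to S_k; derive D
    either through the linear link (default) or a correlated log-normal
    draw; project the triple onto the feasible set; and, when
    ``materialize`` is true, realise it as an exact clone table (optionally
    multinomially subsampled to ``params.depth``).  With ``materialize``
    false, only the metrics table is returned, with S_10 and S_100 derived
    in closed form from the as-even-as-possible top-block profile.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, k = params.n_subjects, params.k

    age, male, cmv_pos, cmv_unknown = _covariate_draw(params, rng)
    sex = np.where(male, "male", "female")
    cmv = np.where(cmv_unknown, "unknown", np.where(cmv_pos, "positive", "negative"))
    cmv_effect = cmv_pos & ~cmv_unknown  # unknowns carry no CMV effect

    mu_s = (
        params.log10_s_median
        + params.age_slope_log10_s * (age - params.reference_age)
        + np.where(male, params.male_offset_log10_s, 0.0)
        + np.where(cmv_effect, params.cmv_offset_log10_s, 0.0)
    )
    # the configured median is the cohort-marginal median: centre the
    # covariate effects so they reshape the cohort without displacing it
    mu_s -= np.median(mu_s) - params.log10_s_median
    z_s = rng.standard_normal(n)
    log10_s = mu_s + params.log10_s_sd * z_s
    S = np.maximum(np.round(10.0 ** log10_s), k + 2).astype(np.int64)

    mu_p = (
        params.p_k_at_age20
        + params.p_k_age_slope * (age - 20.0)
        + np.where(male, 0.0, params.p_k_female_offset)
        + np.where(cmv_effect, params.p_k_cmv_offset, 0.0)
    )
    p_k = np.clip(
        mu_p + params.p_k_noise_sd * rng.standard_normal(n),
        params.p_k_floor,
        params.p_k_ceiling,
    )
    S_k = np.round(p_k / 100.0 * S).astype(np.int64)

    if params.d_link == "linear":
        d_true = params.link_a * S - params.link_b * S_k
        d_true = np.maximum(d_true, k + 1.0)
        log10_d = (
            np.log10(d_true)
            + params.intrinsic_noise_sd * rng.standard_normal(n)
            + params.measurement_noise_sd * rng.standard_normal(n)
        )
    else:
        mu_d = (
            params.log10_d_median
            + params.age_slope_log10_d * (age - params.reference_age)
            + np.where(male, params.male_offset_log10_d, 0.0)
            + np.where(cmv_effect, params.cmv_offset_log10_d, 0.0)
        )
        mu_d -= np.median(mu_d) - params.log10_d_median
        rho = params.s_d_correlation
        z_d = rho * z_s + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
        log10_d = (
            mu_d
            + params.log10_d_sd * z_d
            + params.measurement_noise_sd * rng.standard_normal(n)
        )
    D = np.round(10.0 ** log10_d).astype(np.int64)

    n_projected = 0
    rows = []
    for i in range(n):
        s_i, d_i, sk_i, changed = project_to_feasible(int(S[i]), int(D[i]), int(S_k[i]), k)
        n_projected += changed
        rows.append((s_i, d_i, sk_i))
    if n_projected > 0.5 * n:
        raise ConfigError(
            f"{n_projected}/{n} subjects required feasibility projection; "
            "the configured effects imply inconsistent metric targets"
        )
    if n_projected:
        logger.info("simulate_cohort: projected %d/%d infeasible triples", n_projected, n)

    covariates = [
        SubjectCovariates(
            subject_id=f"subj{i:05d}", age=float(age[i]), sex=str(sex[i]), cmv_status=str(cmv[i])
        )
        for i in range(n)
    ]

    seeds = np.random.SeedSequence(params.seed).spawn(n)
    tables: list[CloneTable] = []
    records = []
    for i, (s_i, d_i, sk_i) in enumerate(rows):
        rec = {
            "subject_id": covariates[i].subject_id,
            "age": covariates[i].age,
            "sex": covariates[i].sex,
            "cmv_status": covariates[i].cmv_status,
        }
        if materialize:
            child = np.random.default_rng(seeds[i])
            table = construct_clone_table(
                MetricTriple(S=s_i, D=d_i, S_k=sk_i, k=k),
                subject_id=covariates[i].subject_id,
                profile=params.profile,
                geometric_decay=params.geometric_decay,
            )
            if params.depth is not None:
                table = subsample_repertoire(
                    table, params.depth, seed=int(child.integers(2**31))
                )
            tables.append(table)
            m = compute_metrics(table, sorted({10, 100, k}))
            measured = {"S": m.S, "D": m.D, "S_10": m.S_k[10], "S_100": m.S_k[100]}
            measured[f"S_{k}"] = m.S_k[k]
            measured[f"P_{k}"] = m.P_k[k]
            rec.update(measured)
        else:
            rec.update(
                S=s_i, D=d_i,
                S_10=_even_top_mass(sk_i, min(k, d_i), 10),
                S_100=_even_top_mass(sk_i, min(k, d_i), 100),
                **{f"S_{k}": sk_i, f"P_{k}": 100.0 * sk_i / s_i},
            )
        records.append(rec)

    metrics = pd.DataFrame.from_records(records)
    return SimulatedCohort(
        clone_tables=tables, covariates=covariates, metrics=metrics,
        n_projected=n_projected, params=params,
    )


def _even_top_mass(S_k: int, k: int, j: int) -> int:
    """Mass of the j largest clones within an even split of S_k over k clones."""
    if j >= k:
        return S_k
    q, r = divmod(S_k, k)
    return j * q + min(j, r)


# ---------------------------------------------------------------------------
# Sequencing subsampling and technical replicates
# ---------------------------------------------------------------------------

def subsample_repertoire(
    table: CloneTable, depth: int, seed: int = 0, replace: bool = True
) -> CloneTable:
    """Resample a repertoire to a fixed sequencing depth.

    With replacement (default): a multinomial draw of ``depth`` templates
    with probabilities proportional to counts.  Without replacement: a
    multivariate hypergeometric draw, requiring depth <= total templates.
    Clones drawn zero times are dropped; the output total is exactly
    ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.templates
    if replace:
        drawn = rng.multinomial(depth, counts / counts.sum())
    else:
        if depth > counts.sum():
            raise ValueError(
                f"depth {depth} exceeds total templates {int(counts.sum())} "
                "for without-replacement sampling"
            )
        drawn = rng.multivariate_hypergeometric(counts, depth)
    keep = drawn > 0
    return CloneTable(
        subject_id=table.subject_id,
        clone_ids=tuple(cid for cid, m in zip(table.clone_ids, keep) if m),
        templates=drawn[keep].astype(np.int64),
    )


def simulate_replicates(
    cohort, noise_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Simulate two technical measurements per subject.

    ``cohort`` is either a list of CloneTable or a metrics DataFrame with
    S and D columns.  Each measurement perturbs log10 D by independent
    Gaussian noise of sd ``noise_sd`` (dex) while S is held fixed, so the
    pair difference in log10(D/S) has sd noise_sd * sqrt(2).  Returns a
    DataFrame with columns subject_id, S_1, D_1, S_2, D_2.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(cohort, pd.DataFrame):
        sids = cohort["subject_id"].astype(str).to_numpy()
        S = cohort["S"].to_numpy(np.int64)
        D = cohort["D"].to_numpy(np.float64)
    else:
        sids = np.array([t.subject_id for t in cohort])
        S = np.array([t.total_templates for t in cohort], np.int64)
        D = np.array([t.n_clones for t in cohort], np.float64)
    rng = np.random.default_rng(seed)
    eps = noise_sd * rng.standard_normal((2, len(S)))
    d1 = np.maximum(np.round(D * 10.0 ** eps[0]), 1).astype(np.int64)
    d2 = np.maximum(np.round(D * 10.0 ** eps[1]), 1).astype(np.int64)
    return pd.DataFrame(
        {"subject_id": sids, "S_1": S, "D_1": d1, "S_2": S, "D_2": d2}
    )


def write_cohort_files(cohort: SimulatedCohort, out_dir) -> None:
    """Write clone tables (simple TSV), covariates CSV, metrics CSV, manifest."""
    import json
    import os

    from .repertoire import write_clone_table, write_cohort_table

    os.makedirs(out_dir, exist_ok=True)
    tdir = os.path.join(out_dir, "clone_tables")
    os.makedirs(tdir, exist_ok=True)
    for table in cohort.clone_tables:
        write_clone_table(table, os.path.join(tdir, f"{table.subject_id}.tsv"))
    pd.DataFrame(
        [
            {"subject_id": c.subject_id, "age": c.age, "sex": c.sex, "cmv_status": c.cmv_status}
            for c in cohort.covariates
        ]
    ).to_csv(os.path.join(out_dir, "covariates.csv"), index=False)
    write_cohort_table(cohort.metrics, os.path.join(out_dir, "metrics.csv"))
    manifest = {
        "params": cohort.params.to_dict() if cohort.params else None,
        "n_projected": cohort.n_projected,
        "n_clone_tables": len(cohort.clone_tables),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
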