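"""Synthetic dialysis cohorts with the hierarchical gamma-SUR structure.

The generator emulates the data layout of a repeated-measures nutrition study
in dialysis patients: ``K`` patients nested in ``L`` dialysis-treatment groups
(hospital hemodialysis, home hemodialysis, peritoneal dialysis), ``n_obs``
observation occasions per patient, ``p`` dietary/medication predictors and
``M`` plasma-concentration responses (plasma potassium, fasting plasma
phosphate, plasma albumin).  Responses follow a shifted gamma distribution
whose mean is an additive linear predictor with nutrient effects that vary at
the treatment and the patient level:

    mu_kmi = a_m + x_ki . (beta_.m + g_l(k),.m + b_k,.m)
    y_kmi + c ~ Gamma(alpha_m, alpha_m / (mu_kmi + c))

Treatment deviations ``g`` and personal deviations ``b`` are drawn from
zero-mean Gaussians with covariance ``Sigma = T C T'`` (standard-deviation
diagonal times correlation matrix), so effects on different predictors and
different responses can be correlated.

Effect vectors of length ``p*M`` are flattened response-major: entry
``d = m*p + j`` is the effect of predictor ``j`` on response ``m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortConfig",
    "CohortData",
    "TrueEffects",
    "default_config",
    "toy_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "random_lkj_corr",
]

#: (name, study mean, min, max, unit) of the continuous nutrient predictors.
CONTINUOUS_PREDICTORS = [
    ("carbohydrates_epct", 43.6, 27.1, 63.6, "E%"),
    ("fat_epct", 38.9, 23.4, 54.1, "E%"),
    ("mufa_epct", 14.7, 5.6, 25.1, "E%"),
    ("pufa_epct", 7.1, 2.2, 15.8, "E%"),
    ("protein_epct", 15.1, 9.2, 22.4, "E%"),
    ("sfa_epct", 13.7, 5.9, 24.5, "E%"),
    ("fiber_g", 17.0, 5.0, 42.0, "g/d"),
    ("protein_g_per_kg", 0.8, 0.2, 2.1, "g/kg/d"),
    ("energy_kcal_per_kg", 21.8, 5.6, 58.6, "kcal/kg/d"),
    ("calcium_mg", 570.0, 123.0, 1741.0, "mg/d"),
    ("sodium_mg", 2588.0, 813.0, 5487.0, "mg/d"),
    ("phosphorus_mg", 1042.0, 304.0, 2184.0, "mg/d"),
    ("potassium_mg", 2785.0, 1026.0, 5713.0, "mg/d"),
    ("salt_mg", 6560.0, 201.0, 13863.0, "mg/d"),
    ("water_ml", 1804.0, 601.0, 3613.0, "ml/d"),
    ("vitamin_d_ug", 8.0, 0.0, 31.0, "ug/d"),
]

#: (name, prevalence) of patient-constant binary covariates.
BINARY_PREDICTORS = [
    ("active_vitamin_d", 0.43),
    ("blood_lipid_med", 0.68),
    ("diabetes_med", 0.51),
    ("phosphate_binder_med", 0.22),
    ("renavit", 0.97),
    ("gender_female", 0.41),
]

RESPONSES = ["p_k", "fp_pi", "p_alb"]
RESPONSE_UNITS = {"p_k": "mmol/l", "fp_pi": "mmol/l", "p_alb": "g/l"}
#: typical plasma levels used to anchor intercepts of the default generator
RESPONSE_BASELINES = {"p_k": 4.0, "fp_pi": 1.5, "p_alb": 40.0}

ID_COLUMNS = ["patient", "treatment", "obs"]


@dataclass
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort."""

    K: int
    L: int
    treatment_sizes: tuple
    n_obs: int
    p: int
    M: int
    beta_true: np.ndarray          # (p, M) effects per raw predictor unit
    intercept_true: np.ndarray     # (M,)
    sigma_g: np.ndarray            # (p*M,) treatment-level effect sds
    sigma_b: np.ndarray            # (p*M,) personal-level effect sds
    C_g: np.ndarray                # (p*M, p*M) correlation matrix
    C_b: np.ndarray
    alpha_true: np.ndarray         # (M,) gamma shapes
    shift_c: float
    intake_mean_range: np.ndarray  # (p, 2) per-predictor patient-mean range
    intake_sd_range: np.ndarray    # (p, 2) per-predictor within-patient sd range
    binary: np.ndarray             # (p,) bool, patient-constant Bernoulli column
    binary_prev: np.ndarray        # (p,) prevalence (ignored for continuous)
    seed: int = 0
    predictor_names: list = field(default_factory=list)
    response_names: list = field(default_factory=lambda: list(RESPONSES))
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, float).reshape(self.p, self.M)
        self.intercept_true = np.asarray(self.intercept_true, float).reshape(self.M)
        self.sigma_g = np.asarray(self.sigma_g, float).reshape(self.p * self.M)
        self.sigma_b = np.asarray(self.sigma_b, float).reshape(self.p * self.M)
        self.C_g = np.asarray(self.C_g, float)
        self.C_b = np.asarray(self.C_b, float)
        self.alpha_true = np.asarray(self.alpha_true, float).reshape(self.M)
        self.intake_mean_range = np.asarray(self.intake_mean_range, float).reshape(self.p, 2)
        self.intake_sd_range = np.asarray(self.intake_sd_range, float).reshape(self.p, 2)
        self.binary = np.asarray(self.binary, bool).reshape(self.p)
        self.binary_prev = np.asarray(self.binary_prev, float).reshape(self.p)
        if not self.predictor_names:
            self.predictor_names = [f"x{j}" for j in range(self.p)]
        if len(self.response_names) != self.M:
            self.response_names = [f"y{m}" for m in range(self.M)]
        self.validate()

    def validate(self):
        if sum(self.treatment_sizes) != self.K:
            raise ValueError(
                f"treatment_sizes {self.treatment_sizes} must sum to K={self.K}"
            )
        if len(self.treatment_sizes) != self.L:
            raise ValueError("treatment_sizes length must equal L")
        if np.any(self.alpha_true <= 0):
            raise ValueError("alpha_true must be positive")
        if np.any(self.sigma_g < 0) or np.any(self.sigma_b < 0):
            raise ValueError("sigma_g and sigma_b must be non-negative")
        if self.shift_c < 0:
            raise ValueError("shift_c must be >= 0")
        for name, C in (("C_g", self.C_g), ("C_b", self.C_b)):
            d = self.p * self.M
            if C.shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError(f"{name} must have unit diagonal")
            w = np.linalg.eigvalsh(C)
            if w.min() <= 1e-10:
                raise ValueError(
                    f"{name} is not positive definite "
                    f"(smallest eigenvalue {w.min():.3e})"
                )


@dataclass
class TrueEffects:
    """Every sampled quantity of a generated cohort, for recovery tests."""

    beta: np.ndarray       # (p, M)
    intercept: np.ndarray  # (M,)
    g: np.ndarray          # (L, M, p) treatment-level deviations
    b: np.ndarray          # (K, M, p) personal-level deviations
    alpha: np.ndarray      # (M,)
    shift_c: float
    mu: np.ndarray         # (N, M) generating means per observation row

    def coef(self, k: int, treatment: int) -> np.ndarray:
        """Personal-level coefficient matrix beta + g_l + b_k, shape (M, p)."""
        return self.beta.T + self.g[treatment] + self.b[k]


class CohortData:
    """Long-format repeated observations of a (synthetic or real) cohort.

    One row per (patient, observation occasion).  Response cells may be
    missing; ``status`` tracks "observed" / "missing" / "imputed".
    """

    def __init__(self, df, predictor_names, response_names, units=None,
                 binary=None):
        self.df = df.reset_index(drop=True)
        self.predictor_names = list(predictor_names)
        self.response_names = list(response_names)
        self.units = dict(units or {})
        if binary is None:
            binary = np.zeros(len(self.predictor_names), bool)
        self.binary = np.asarray(binary, bool)
        self._validate()

    def _validate(self):
        missing = [c for c in ID_COLUMNS + self.predictor_names
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns {missing}")
        treat = self.df.groupby("patient")["treatment"].nunique()
        if (treat > 1).any():
            bad = treat[treat > 1].index.tolist()
            raise ValueError(f"patients {bad} map to more than one treatment")
        dup = self.df.duplicated(subset=["patient", "obs"])
        if dup.any():
            raise ValueError(
                f"duplicate (patient, obs) pairs at rows {list(self.df.index[dup])}"
            )
        for r in self.response_names:
            if f"{r}_status" not in self.df.columns:
                self.df[f"{r}_status"] = np.where(
                    self.df[r].notna(), "observed", "missing")

    # -- accessors ---------------------------------------------------------
    @property
    def n_rows(self):
        return len(self.df)

    @property
    def patients(self):
        return np.unique(self.df["patient"].to_numpy())

    @property
    def n_patients(self):
        return len(self.patients)

    def x_matrix(self):
        return self.df[self.predictor_names].to_numpy(float)

    def y_matrix(self):
        return self.df[self.response_names].to_numpy(float)

    def mask(self):
        """Boolean (N, M): True where the response was actually observed."""
        return np.column_stack([
            (self.df[f"{r}_status"] == "observed").to_numpy()
            for r in self.response_names])

    def status(self):
        return np.column_stack([
            self.df[f"{r}_status"].to_numpy() for r in self.response_names])

    def treatment_of(self, patient):
        sub = self.df.loc[self.df["patient"] == patient, "treatment"]
        if sub.empty:
            raise KeyError(f"unknown patient {patient}")
        return int(sub.iloc[0])

    def patient_rows(self, patient):
        return np.flatnonzero((self.df["patient"] == patient).to_numpy())

    def subset_patients(self, keep):
        keep = set(int(k) for k in keep)
        sub = self.df[self.df["patient"].isin(keep)].copy()
        return CohortData(sub, self.predictor_names, self.response_names,
                          self.units, self.binary)

    def copy(self):
        return CohortData(self.df.copy(), self.predictor_names,
                          self.response_names, self.units, self.binary)

    def equals(self, other):
        try:
            pd.testing.assert_frame_equal(
                self.df[ID_COLUMNS + self.predictor_names + self.response_names
                        + [f"{r}_status" for r in self.response_names]],
                other.df[ID_COLUMNS + other.predictor_names + other.response_names
                         + [f"{r}_status" for r in other.response_names]],
                check_dtype=False)
        except AssertionError:
            return False
        return (self.predictor_names == other.predictor_names
                and self.response_names == other.response_names)


# ---------------------------------------------------------------------------
# configuration factories


def random_lkj_corr(d, eta, rng):
    """Random correlation matrix via the onion method (LKJ(eta) distributed)."""
    if d == 1:
        return np.ones((1, 1))
    beta = eta + (d - 2) / 2.0
    r = 2 * rng.beta(beta, beta) - 1
    C = np.array([[1.0, r], [r, 1.0]])
    for k in range(2, d):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        u = rng.standard_normal(k)
        u /= np.linalg.norm(u)
        w = np.sqrt(y) * u
        A = np.linalg.cholesky(C)
        z = A @ w
        C = np.block([[C, z[:, None]], [z[None, :], np.ones((1, 1))]])
    return C


def _make_config(names, units, means, mean_rng, sd_rng, binary, prev,
                 K, L, sizes, n_obs, M, sigma_frac_g, sigma_frac_b,
                 corr_g, corr_b, alpha, seed, beta_seed, effect_frac=0.1):
    """Shared construction: anchors effect scales to predictor/response scales.

    A "typical" effect of predictor j on response m moves response m by about
    ``effect_frac`` of its baseline when predictor j moves by one sd, with the
    total over p predictors kept at the same order via the 1/sqrt(p) factor.
    """
    p = len(names)
    resp = RESPONSES[:M] if M <= 3 else [f"y{m}" for m in range(M)]
    base = np.array([RESPONSE_BASELINES.get(r, 1.0) for r in resp])
    # predictor sd implied by the patient-mean sampling range / prevalence
    sd_j = np.where(binary, np.sqrt(np.clip(prev * (1 - prev), 1e-4, None)),
                    (mean_rng[:, 1] - mean_rng[:, 0]) / np.sqrt(12.0))
    ref_scale = effect_frac * base[None, :] / (sd_j[:, None] * np.sqrt(p))
    rng_b = np.random.default_rng(beta_seed)
    beta = rng_b.standard_normal((p, M)) * ref_scale
    sigma_g = (sigma_frac_g * ref_scale).T.reshape(p * M)  # response-major
    sigma_b = (sigma_frac_b * ref_scale).T.reshape(p * M)
    intercept = base - means @ beta
    d = p * M
    C_g = np.eye(d) if corr_g is None else corr_g
    C_b = np.eye(d) if corr_b is None else corr_b
    return CohortConfig(
        K=K, L=L, treatment_sizes=tuple(sizes), n_obs=n_obs, p=p, M=M,
        beta_true=beta, intercept_true=intercept,
        sigma_g=sigma_g, sigma_b=sigma_b, C_g=C_g, C_b=C_b,
        alpha_true=np.full(M, alpha), shift_c=0.0,
        intake_mean_range=mean_rng, intake_sd_range=sd_rng,
        binary=binary, binary_prev=prev, seed=seed,
        predictor_names=list(names), response_names=resp, units=units,
    )


def default_config(seed=0, sigma_frac_g=0.3, sigma_frac_b=0.3, alpha=50.0,
                   corr_g=None, corr_b=None):
    """Cohort mirroring the study layout: K=37 patients in groups 21/9/7,
    two observations each, 22 predictors, three plasma responses."""
    names = [n for n, *_ in CONTINUOUS_PREDICTORS] + [n for n, _ in BINARY_PREDICTORS]
    units = {n: u for n, _, _, _, u in CONTINUOUS_PREDICTORS}
    units.update(RESPONSE_UNITS)
    n_cont = len(CONTINUOUS_PREDICTORS)
    p = len(names)
    lo = np.array([mn for _, _, mn, _, _ in CONTINUOUS_PREDICTORS] + [0.0] * 6)
    hi = np.array([mx for _, _, _, mx, _ in CONTINUOUS_PREDICTORS] + [1.0] * 6)
    means = np.array([m for _, m, _, _, _ in CONTINUOUS_PREDICTORS]
                     + [pr for _, pr in BINARY_PREDICTORS])
    mean_rng = np.column_stack([lo, hi])
    width = hi - lo
    # within-patient day-to-day variation: 5-15 % of the intake range
    sd_rng = np.column_stack([0.05 * width, 0.15 * width])
    binary = np.array([False] * n_cont + [True] * 6)
    prev = np.array([0.0] * n_cont + [pr for _, pr in BINARY_PREDICTORS])
    return _make_config(names, units, means, mean_rng, sd_rng, binary, prev,
                        K=37, L=3, sizes=(21, 9, 7), n_obs=2, M=3,
                        sigma_frac_g=sigma_frac_g, sigma_frac_b=sigma_frac_b,
                        corr_g=corr_g, corr_b=corr_b,
                        alpha=alpha, seed=seed, beta_seed=20180301)


def toy_config(K=12, L=3, sizes=None, n_obs=4, p=5, M=3, sigma_frac_g=0.3,
               sigma_frac_b=0.3, alpha=50.0, seed=0, corr_g=None,
               corr_b=None, n_binary=0, beta_seed=1234):
    """Small cohort for fast fits and recovery studies; O(1)-scale intakes."""
    if sizes is None:
        base, extra = divmod(K, L)
        sizes = tuple(base + (1 if l < extra else 0) for l in range(L))
    names = [f"x{j}" for j in range(p)]
    binary = np.array([j >= p - n_binary for j in range(p)])
    prev = np.where(binary, 0.5, 0.0)
    mean_rng = np.tile(np.array([2.0, 8.0]), (p, 1))
    mean_rng[binary] = [0.0, 1.0]
    sd_rng = np.tile(np.array([0.3, 0.9]), (p, 1))
    means = np.where(binary, prev, 5.0)
    units = {r: RESPONSE_UNITS.get(r, "") for r in RESPONSES[:M]}
    return _make_config(names, units, means, mean_rng, sd_rng, binary, prev,
                        K=K, L=L, sizes=sizes, n_obs=n_obs, M=M,
                        sigma_frac_g=sigma_frac_g, sigma_frac_b=sigma_frac_b,
                        corr_g=corr_g, corr_b=corr_b,
                        alpha=alpha, seed=seed, beta_seed=beta_seed)


# ---------------------------------------------------------------------------
# generation


def _draw_effects(sigma, C, n, rng):
    d = len(sigma)
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(C)
        raise ValueError(
            f"correlation matrix not positive definite "
            f"(smallest eigenvalue {w.min():.3e})")
    z = rng.standard_normal((n, d))
    return (sigma * (z @ Lc.T))  # rows ~ N(0, T C T')


def generate_cohort(config: CohortConfig):
    """Draw a full synthetic cohort; returns (CohortData, TrueEffects).

    Responses are generated on the shifted scale, ``y + c ~ Gamma``, and the
    shift subtracted afterwards, so the generating model and the fitted model
    coincide exactly.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p, M, K = cfg.p, cfg.M, cfg.K

    g_flat = _draw_effects(cfg.sigma_g, cfg.C_g, cfg.L, rng)   # (L, pM)
    b_flat = _draw_effects(cfg.sigma_b, cfg.C_b, K, rng)       # (K, pM)
    g = g_flat.reshape(cfg.L, M, p)
    b = b_flat.reshape(K, M, p)

    treatment = np.repeat(np.arange(cfg.L), cfg.treatment_sizes)

    # per-patient latent intake means and within-patient sds
    lo, hi = cfg.intake_mean_range[:, 0], cfg.intake_mean_range[:, 1]
    pat_mean = rng.uniform(lo, hi, size=(K, p))
    slo, shi = cfg.intake_sd_range[:, 0], cfg.intake_sd_range[:, 1]
    pat_sd = rng.uniform(slo, shi, size=(K, p))
    bern = (rng.uniform(size=(K, p)) < cfg.binary_prev).astype(float)

    rows = []
    mu_all = np.empty((K * cfg.n_obs, M))
    y_all = np.empty((K * cfg.n_obs, M))
    r = 0
    for k in range(K):
        coef = cfg.beta_true.T + g[treatment[k]] + b[k]  # (M, p)
        for i in range(cfg.n_obs):
            x = np.where(
                cfg.binary, bern[k],
                _truncnorm(pat_mean[k], pat_sd[k], rng))
            mu = cfg.intercept_true + coef @ x
            if np.any(mu + cfg.shift_c <= 0):
                m_bad = int(np.argmin(mu))
                raise ValueError(
                    f"mu + shift_c <= 0 for patient {k}, response "
                    f"{cfg.response_names[m_bad]} (mu={mu[m_bad]:.4g}); "
                    f"increase shift_c above {-mu.min():.4g}")
            shape = cfg.alpha_true
            y = rng.gamma(shape, (mu + cfg.shift_c) / shape) - cfg.shift_c
            mu_all[r], y_all[r] = mu, y
            rows.append((k, treatment[k], i, *x))
            r += 1

    df = pd.DataFrame(rows, columns=ID_COLUMNS + cfg.predictor_names)
    for m, rname in enumerate(cfg.response_names):
        df[rname] = y_all[:, m]
        df[f"{rname}_status"] = "observed"
    data = CohortData(df, cfg.predictor_names, cfg.response_names,
                      cfg.units, cfg.binary)
    truth = TrueEffects(beta=cfg.beta_true.copy(),
                        intercept=cfg.intercept_true.copy(),
                        g=g, b=b, alpha=cfg.alpha_true.copy(),
                        shift_c=cfg.shift_c, mu=mu_all)
    return data, truth


def _truncnorm(mean, sd, rng):
    """Normal draws truncated at zero (intakes cannot be negative)."""
    sd = np.maximum(sd, 1e-12)
    a = (0.0 - mean) / sd
    u = rng.uniform(size=mean.shape)
    lo = stats.norm.cdf(a)
    return mean + sd * stats.norm.ppf(lo + u * (1 - lo))


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: CohortData, path, truth: TrueEffects | None = None,
                 config: CohortConfig | None = None):
    """Write the long-format table as CSV plus a JSON schema sidecar."""
    path = Path(path)
    cols = ID_COLUMNS + cohort.predictor_names + list(cohort.response_names)
    out = cohort.df[cols].copy()
    for r in cohort.response_names:
        out[r] = np.where(cohort.df[f"{r}_status"] == "missing",
                          np.nan, out[r])
        out[f"{r}_status"] = cohort.df[f"{r}_status"]
    out.to_csv(path, index=False, na_rep="NA")
    meta = {
        "predictor_names": cohort.predictor_names,
        "response_names": cohort.response_names,
        "units": cohort.units,
        "binary": cohort.binary.astype(int).tolist(),
    }
    if truth is not None:
        meta["true_effects"] = {
            "beta": truth.beta.tolist(), "intercept": truth.intercept.tolist(),
            "g": truth.g.tolist(), "b": truth.b.tolist(),
            "alpha": truth.alpha.tolist(), "shift_c": truth.shift_c,
        }
    if config is not None:
        meta["config"] = {
            "K": config.K, "L": config.L,
            "treatment_sizes": list(config.treatment_sizes),
            "n_obs": config.n_obs, "p": config.p, "M": config.M,
            "seed": config.seed, "shift_c": config.shift_c,
            "alpha_true": config.alpha_true.tolist(),
        }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_cohort(path):
    """Read a cohort CSV (plus sidecar schema if present); inverse of
    :func:`write_cohort`."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    try:
        df = pd.read_csv(path, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        pred = meta["predictor_names"]
        resp = meta["response_names"]
        expected = set(ID_COLUMNS) | set(pred) | set(resp) | {
            f"{r}_status" for r in resp}
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            raise ValueError(
                f"unknown columns {unknown}; expected schema: "
                f"{ID_COLUMNS} + predictors {pred} + responses {resp} "
                f"(+ optional <response>_status)")
        units = meta.get("units", {})
        binary = np.asarray(meta.get("binary", [0] * len(pred)), bool)
    else:
        resp = [c for c in RESPONSES if c in df.columns]
        if not resp:
            resp = [df.columns[-1]]
        status_cols = [c for c in df.columns if c.endswith("_status")]
        pred = [c for c in df.columns
                if c not in ID_COLUMNS + resp + status_cols]
        units, binary = {}, None
    for c in ID_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"cohort file lacks required column '{c}'")
    for r in resp:
        neg = df.index[df[r].notna() & (df[r] <= 0)]
        if len(neg):
            raise ValueError(
                f"non-positive concentration {r}={df.loc[neg[0], r]} "
                f"at row {int(neg[0])}; concentrations must be > 0")
        if f"{r}_status" not in df.columns:
            df[f"{r}_status"] = np.where(df[r].notna(), "observed", "missing")
    return CohortData(df, pred, resp, units, binary)
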