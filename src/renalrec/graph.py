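"""Per-patient generative graphical models.

A patient's graph combines (i) intake nodes — Normal distributions estimated
from the patient's observed intakes, (ii) effect values at the personal level
of the hierarchy (draw-aligned posterior samples of beta + g_l + b_k), and
(iii) gamma response nodes for the plasma concentrations, with the patient's
target normal ranges attached.  Simulating the graph under the current diet
should reproduce the measured concentrations; conditioning it on the targets
is the recommendation query handled in :mod:`renalrec.recommend`.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

__all__ = ["IntakeDistribution", "NormalRanges", "PersonalGraph",
           "ConcentrationDraws", "estimate_intakes", "build_graph",
           "simulate_current", "impute_missing"]

#: fraction of the mean intake used as the sd floor for degenerate estimates
SD_FLOOR_FRAC = 0.05


@dataclass
class IntakeDistribution:
    """Normal model of a patient's current intakes: X_j ~ N(mean_j, sd_j^2),
    truncated at zero when sampled (negative intake is impossible)."""
    patient: int
    names: list
    mean: np.ndarray
    sd: np.ndarray
    n_obs: int

    def sample(self, size, rng):
        """(size, p) truncated-normal draws."""
        sd = np.maximum(self.sd, 1e-12)
        a = (0.0 - self.mean) / sd
        lo = stats.norm.cdf(a)
        u = rng.uniform(size=(size, len(self.mean)))
        return self.mean + sd * stats.norm.ppf(lo + u * (1.0 - lo))

    def quantile(self, q):
        """Pointwise quantile (not truncated), floored at zero."""
        return np.maximum(self.mean + self.sd * stats.norm.ppf(q), 0.0)


@dataclass
class NormalRanges:
    """Target concentration ranges per response; albumin bounds depend on the
    patient's age (36-48 g/l up to 39 y, 36-45 for 40-69 y, 34-45 from 70 y)."""
    lower: dict
    upper: dict

    @classmethod
    def for_age(cls, age=None):
        lower = {"p_k": 3.4, "fp_pi": 1.13}
        upper = {"p_k": 4.7, "fp_pi": 1.78}
        if age is None or 40 <= age <= 69:
            lower["p_alb"], upper["p_alb"] = 36.0, 45.0
        elif age <= 39:
            lower["p_alb"], upper["p_alb"] = 36.0, 48.0
        else:
            lower["p_alb"], upper["p_alb"] = 34.0, 45.0
        return cls(lower=lower, upper=upper)

    def bounds(self, response):
        return self.lower[response], self.upper[response]

    @classmethod
    def from_yaml(cls, path, age=None):
        """YAML keyed by response; albumin may be keyed by age bracket
        "<=39" / "40-69" / ">=70"."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lower, upper = {}, {}
        for resp, val in raw.items():
            if isinstance(val, dict) and "lower" not in val:
                if age is None:
                    raise ValueError(
                        f"range for {resp} is age-dependent; age required")
                key = ("<=39" if age <= 39 else
                       "40-69" if age <= 69 else ">=70")
                val = val[key]
            lower[resp], upper[resp] = float(val["lower"]), float(val["upper"])
        return cls(lower=lower, upper=upper)

    def to_yaml(self, path):
        out = {r: {"lower": self.lower[r], "upper": self.upper[r]}
               for r in self.lower}
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh)


@dataclass
class PersonalGraph:
    """Fully estimated generative model G_k for one patient."""
    patient: int
    treatment: int
    intakes: IntakeDistribution
    effect_draws: np.ndarray      # (S, M, p) beta + g_l + b_k, draw-aligned
    intercept_draws: np.ndarray   # (S, M)
    alpha_draws: np.ndarray       # (S, M) gamma shapes
    shift_c: float
    ranges: NormalRanges
    predictor_names: list = field(default_factory=list)
    response_names: list = field(default_factory=list)

    @property
    def p(self):
        return len(self.predictor_names)

    @property
    def M(self):
        return len(self.response_names)

    def effect_point(self, l_beta=0.5):
        """(M, p) point effects: posterior mean at l=0.5, tail quantile else."""
        if l_beta == 0.5:
            return self.effect_draws.mean(axis=0)
        return np.quantile(self.effect_draws, l_beta, axis=0)

    def intercept_point(self):
        return self.intercept_draws.mean(axis=0)

    def alpha_point(self):
        return self.alpha_draws.mean(axis=0)

    def to_networkx(self):
        import networkx as nx
        G = nx.DiGraph()
        eff = self.effect_draws
        for j, name in enumerate(self.predictor_names):
            G.add_node(("intake", name), mean=float(self.intakes.mean[j]),
                       sd=float(self.intakes.sd[j]))
        for m, resp in enumerate(self.response_names):
            G.add_node(("response", resp),
                       alpha=float(self.alpha_draws[:, m].mean()),
                       lower=self.ranges.lower.get(resp),
                       upper=self.ranges.upper.get(resp))
            for j, name in enumerate(self.predictor_names):
                G.add_edge(("intake", name), ("response", resp),
                           effect_mean=float(eff[:, m, j].mean()),
                           effect_sd=float(eff[:, m, j].std(ddof=1)))
        return G

    def to_json_dict(self):
        return {
            "patient": int(self.patient), "treatment": int(self.treatment),
            "shift_c": self.shift_c,
            "intakes": {n: {"mean": float(m), "sd": float(s)}
                        for n, m, s in zip(self.predictor_names,
                                           self.intakes.mean,
                                           self.intakes.sd)},
            "effects": {
                resp: {pred: {"mean": float(self.effect_draws[:, m, j].mean()),
                              "sd": float(self.effect_draws[:, m, j].std(ddof=1))}
                       for j, pred in enumerate(self.predictor_names)}
                for m, resp in enumerate(self.response_names)},
            "alpha": {r: float(self.alpha_draws[:, m].mean())
                      for m, r in enumerate(self.response_names)},
            "ranges": {r: list(self.ranges.bounds(r))
                       for r in self.response_names
                       if r in self.ranges.lower},
        }


def estimate_intakes(cohort, patient, sd_floor_frac=SD_FLOOR_FRAC
                     ) -> IntakeDistribution:
    """Per-predictor Normal from the patient's observations: sample mean and
    sample sd (n-1); degenerate cases floored at sd_floor_frac * |mean|."""
    rows = cohort.patient_rows(patient)
    if rows.size == 0:
        raise KeyError(f"unknown patient {patient}")
    X = cohort.x_matrix()[rows]
    mean = X.mean(axis=0)
    if len(rows) >= 2:
        sd = X.std(axis=0, ddof=1)
    else:
        sd = np.zeros(X.shape[1])
    floor = np.maximum(sd_floor_frac * np.abs(mean), 1e-9)
    sd = np.maximum(sd, floor)
    return IntakeDistribution(patient=int(patient),
                              names=list(cohort.predictor_names),
                              mean=mean, sd=sd, n_obs=len(rows))


def build_graph(post, cohort, patient, ranges: NormalRanges | None = None,
                b_hat=None) -> PersonalGraph:
    """Assemble G_k from the fitted posterior: personal-level effect draws
    (the most detailed level of the hierarchy) plus the intake model.

    ``b_hat``: optional (M, p) personal deviations for a patient absent from
    the fit (then effect draws carry beta + g_l plus the fixed b_hat).
    """
    treatment = cohort.treatment_of(patient)
    intakes = estimate_intakes(cohort, patient)
    try:
        eff = post.personal_coef_draws(patient)
    except KeyError:
        if b_hat is None:
            raise
        lab_pos = {int(t): i for i, t in enumerate(post.treat_labels)}
        coef = post.stacked("beta").transpose(0, 2, 1).copy()
        if "g" in post.draws:
            coef += post.stacked("g")[:, lab_pos[treatment]]
        eff = coef + b_hat[None, :, :]
    if ranges is None:
        ranges = NormalRanges.for_age(None)
    # per-patient intercept on the raw-intake scale: the fitted deviations act
    # on centered predictors, so the centering term uses this patient's
    # draw-aligned personal coefficients
    a_std = post.stacked("intercept_std")
    intercepts = a_std - np.einsum("smp,p->sm", eff,
                                   post.standardizer.center)
    return PersonalGraph(
        patient=int(patient), treatment=int(treatment), intakes=intakes,
        effect_draws=eff, intercept_draws=intercepts,
        alpha_draws=post.alpha_draws(), shift_c=post.shift_c, ranges=ranges,
        predictor_names=list(post.predictor_names),
        response_names=list(post.response_names))


@dataclass
class ConcentrationDraws:
    y: np.ndarray          # (n, M) simulated concentrations
    mu: np.ndarray         # (n, M) underlying means
    rejections: int        # draws resampled because mu + shift_c <= 0


def simulate_current(graph: PersonalGraph, n_draws, seed=0,
                     max_resample=1000) -> ConcentrationDraws:
    """Simulate concentrations under the patient's current diet: draw intakes
    from their Normals, combine with draw-aligned effects, sample the shifted
    gamma response."""
    M = graph.M
    if n_draws == 0:
        return ConcentrationDraws(np.empty((0, M)), np.empty((0, M)), 0)
    rng = np.random.default_rng(seed)
    S = graph.effect_draws.shape[0]
    y = np.empty((n_draws, M))
    mu_out = np.empty((n_draws, M))
    rejections = 0
    filled = 0
    while filled < n_draws:
        want = n_draws - filled
        idx = rng.integers(0, S, size=want)
        x = graph.intakes.sample(want, rng)
        mu = graph.intercept_draws[idx] + np.einsum(
            "smp,sp->sm", graph.effect_draws[idx], x)
        ok = np.all(mu + graph.shift_c > 0, axis=1)
        n_ok = int(ok.sum())
        rejections += want - n_ok
        if n_ok == 0:
            if rejections > max_resample * n_draws:
                raise RuntimeError(
                    "simulate_current: mu + shift_c <= 0 for nearly all "
                    "draws; shift_c is too small for this graph")
            continue
        shape = graph.alpha_draws[idx][ok]
        mu_ok = mu[ok]
        y[filled:filled + n_ok] = rng.gamma(
            shape, (mu_ok + graph.shift_c) / shape) - graph.shift_c
        mu_out[filled:filled + n_ok] = mu_ok
        filled += n_ok
    return ConcentrationDraws(y=y, mu=mu_out, rejections=rejections)


def impute_missing(post, cohort):
    """Replace missing response cells with their posterior-predictive
    expected values (the posterior-mean concentration at the observed
    predictors, personal level); provenance is flagged as "imputed".

    Observation rows with every response missing are left untouched (there is
    no within-row information to condition on), with a warning.
    """
    from .model import predict_mu
    out = cohort.copy()
    mask = out.mask()
    status = out.status()
    if mask.all():
        return out
    mu = predict_mu(post, out)
    resp = post.response_names
    n_all_missing = 0
    for n in range(out.n_rows):
        row_missing = [m for m, r in enumerate(resp)
                       if status[n, cohort.response_names.index(r)] == "missing"]
        if len(row_missing) == len(resp):
            n_all_missing += 1
            continue
        for m in row_missing:
            rname = resp[m]
            out.df.loc[n, rname] = mu[n, m]
            out.df.loc[n, f"{rname}_status"] = "imputed"
    if n_all_missing:
        _warnings.warn(
            f"{n_all_missing} observation row(s) had all responses missing "
            "and were left unimputed")
    return out
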