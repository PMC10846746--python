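"""Model evaluation: NRMSE scoring, out-of-sample personal-effect prediction,
patient-level cross-validation, and model-variant comparison.

NRMSE aggregates per patient-and-response, normalizing the RMSE of predicted
concentrations by the patient's mean observed concentration:

    NRMSE_km = sqrt(mean_i (yhat_kmi - y_kmi)^2) / ybar_km
    NRMSE_k  = mean_m NRMSE_km,     NRMSE = mean_k NRMSE_k

For a patient absent from a fit, personal effect deviations are predicted as
b_hat = T_b L_b z_hat where z_hat maximizes the standard-normal log prior of
z plus the gamma log likelihood of the patient's observations, holding the
general effects, treatment effects, effect sds and correlations at their
posterior means (common and treatment effects "remain as modeled").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import dlogpdf_dmu, gamma_shifted_logpdf
from .model import ModelSpec, SamplerConfig, fit, predict_mu

__all__ = ["NRMSEReport", "FoldPlan", "nrmse", "make_folds",
           "predict_personal_effects", "cross_validate", "compare_variants"]


@dataclass
class NRMSEReport:
    per_km: pd.DataFrame        # columns patient, response, nrmse
    per_k: pd.Series            # patient -> mean over responses
    overall: float
    variant: str = ""

    def per_response(self):
        return self.per_km.groupby("response")["nrmse"].mean()


def nrmse(predicted, observed, patients, response_names=None, mask=None,
          variant="") -> NRMSEReport:
    """Eq-style NRMSE aggregation; masked cells are excluded, and a
    patient-response pair with zero mean observed concentration is an error
    (the normalization is undefined)."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    patients = np.asarray(patients)
    N, M = observed.shape
    if response_names is None:
        response_names = [f"y{m}" for m in range(M)]
    if mask is None:
        mask = ~np.isnan(observed)
    rows = []
    for k in np.unique(patients):
        sel = patients == k
        for m, resp in enumerate(response_names):
            use = sel & mask[:, m]
            if not use.any():
                continue
            ybar = observed[use, m].mean()
            if ybar == 0:
                raise ValueError(
                    f"mean observed concentration is zero for patient {k}, "
                    f"response {resp}: NRMSE undefined")
            rmse = np.sqrt(np.mean((predicted[use, m] - observed[use, m]) ** 2))
            rows.append((int(k), resp, rmse / abs(ybar)))
    per_km = pd.DataFrame(rows, columns=["patient", "response", "nrmse"])
    per_k = per_km.groupby("patient")["nrmse"].mean()
    return NRMSEReport(per_km=per_km, per_k=per_k,
                       overall=float(per_k.mean()), variant=variant)


@dataclass
class FoldPlan:
    folds: list                 # list of arrays of patient ids (held out)
    n_folds: int
    seed: int

    def validate(self, cohort):
        all_pat = np.concatenate(self.folds)
        if sorted(all_pat.tolist()) != sorted(cohort.patients.tolist()):
            raise ValueError("folds must partition the patients")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")
        treat = {int(k): cohort.treatment_of(k) for k in cohort.patients}
        counts = pd.Series(treat).value_counts()
        for i, f in enumerate(self.folds):
            removed = pd.Series([treat[int(k)] for k in f]).value_counts()
            for t, c in removed.items():
                if c >= counts[t]:
                    raise ValueError(
                        f"fold {i} empties treatment group {t}; treatment "
                        "effects would be unidentifiable")


def make_folds(cohort, n_folds, seed=0) -> FoldPlan:
    """Seeded random partition of patients, stratified by treatment so that
    folds are balanced and no fold empties a treatment group."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = []
    for t in np.unique([cohort.treatment_of(k) for k in cohort.patients]):
        pats = [k for k in cohort.patients if cohort.treatment_of(k) == t]
        pats = list(rng.permutation(pats))
        order.extend(pats)
    folds = [[] for _ in range(n_folds)]
    for i, k in enumerate(order):
        folds[i % n_folds].append(int(k))
    plan = FoldPlan(folds=[np.array(f, int) for f in folds],
                    n_folds=n_folds, seed=seed)
    plan.validate(cohort)
    return plan


def predict_personal_effects(post, new_obs, method="mode", n_mc=2000,
                             seed=0):
    """Predict personal effect deviations b_hat for patients not in the fit.

    ``method="mode"``: z_hat maximizes N(0,I) log prior + gamma log
    likelihood (L-BFGS with analytic gradient); ``method="mean"``: the
    conditional mean of z estimated by self-normalized importance sampling
    from the prior.  Returns dict patient -> (M, p) deviations on the
    original predictor scale.
    """
    beta = post.stacked("beta").mean(axis=0)            # (p, M)
    M_ = len(post.response_names)
    a = post.stacked("intercept_std").reshape(-1, M_).mean(axis=0)
    alpha = post.alpha_draws().mean(axis=0)
    la = np.log(alpha)
    g_mean = post.stacked("g").mean(axis=0) if "g" in post.draws else None
    sigma = post.stacked("sigma_b").mean(axis=0)        # (M, p) original scale
    L_b = post.stacked("L_b").mean(axis=0)              # (pM, pM)
    # renormalize the averaged Cholesky rows to keep unit-norm rows
    rn = np.linalg.norm(L_b, axis=1)
    L_b = L_b / np.where(rn > 0, rn, 1.0)[:, None]
    T = sigma.reshape(-1)                               # response-major (pM,)
    A_mat = T[:, None] * L_b
    p = len(post.predictor_names)
    M = len(post.response_names)
    pM = p * M
    lab_pos = {int(t): i for i, t in enumerate(post.treat_labels)}
    resp_idx = [new_obs.response_names.index(r) for r in post.response_names]

    out = {}
    for k in new_obs.patients:
        rows = new_obs.patient_rows(k)
        X = new_obs.df[post.predictor_names].to_numpy(float)[rows]
        Xc = X - post.standardizer.center               # deviations act on
        y = new_obs.y_matrix()[rows][:, resp_idx]       # centered predictors
        mask = new_obs.mask()[rows][:, resp_idx]
        base = beta.T.copy()                            # (M, p)
        if g_mean is not None:
            base = base + g_mean[lab_pos[new_obs.treatment_of(k)]]
        mu0 = a[None, :] + Xc @ base.T                  # (n, M)

        def neg_logpost(z):
            b = (A_mat @ z).reshape(M, p)
            mu = mu0 + Xc @ b.T
            if np.any(mu[mask] + post.shift_c <= 0):
                return np.inf, np.zeros(pM)
            ll = gamma_shifted_logpdf(np.where(mask, y, 1.0), mu,
                                      la[None, :], post.shift_c)
            val = 0.5 * z @ z - float(ll[mask].sum())
            dmu = np.where(mask, dlogpdf_dmu(y, mu, alpha[None, :],
                                             post.shift_c), 0.0)
            gb = (dmu[:, :, None] * Xc[:, None, :]).sum(axis=0).reshape(pM)
            grad = z - A_mat.T @ gb
            return val, grad

        if not mask.any():
            out[int(k)] = np.zeros((M, p))
            continue
        if method == "mode":
            res = minimize(neg_logpost, np.zeros(pM), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": 500, "gtol": 1e-6})
            if not res.success and np.linalg.norm(res.jac) > 1e-2:
                raise RuntimeError(
                    f"personal-effect optimization did not converge for "
                    f"patient {k} (gradient norm {np.linalg.norm(res.jac):.3g})")
            z_hat = res.x
        elif method == "mean":
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((n_mc, pM))
            logw = np.empty(n_mc)
            for i in range(n_mc):
                b = (A_mat @ Z[i]).reshape(M, p)
                mu = mu0 + Xc @ b.T
                if np.any(mu[mask] + post.shift_c <= 0):
                    logw[i] = -np.inf
                    continue
                ll = gamma_shifted_logpdf(np.where(mask, y, 1.0), mu,
                                          la[None, :], post.shift_c)
                logw[i] = float(ll[mask].sum())
            w = np.exp(logw - logw.max())
            w /= w.sum()
            z_hat = w @ Z
        else:
            raise ValueError("method must be 'mode' or 'mean'")
        out[int(k)] = (A_mat @ z_hat).reshape(M, p)
    return out


def cross_validate(cohort, spec=None, folds=None, sampler=None,
                   n_folds=10, seed=0):
    """Patient-level k-fold CV.  Returns (in-sample report, CV report).

    In-sample predictions use the full-data fit at posterior means; held-out
    patients' concentrations are predicted with their optimized personal
    deviations under the retained fit.
    """
    spec = spec or ModelSpec()
    sampler = sampler or SamplerConfig()
    if folds is None:
        folds = make_folds(cohort, n_folds, seed)
    folds.validate(cohort)
    resp = spec.responses or cohort.response_names

    full_post = fit(cohort, spec, sampler)
    mu_in = predict_mu(full_post, cohort)
    y = cohort.y_matrix()[:, [cohort.response_names.index(r) for r in resp]]
    mask = cohort.mask()[:, [cohort.response_names.index(r) for r in resp]]
    pats = cohort.df["patient"].to_numpy()
    in_report = nrmse(mu_in, y, pats, resp, mask, variant="in_sample")

    rows_pred = np.full_like(y, np.nan)
    for f, held in enumerate(folds.folds):
        train = cohort.subset_patients(
            [k for k in cohort.patients if k not in set(held)])
        test = cohort.subset_patients(held)
        post_f = fit(train, spec, sampler)
        b_hat = predict_personal_effects(post_f, test)
        mu_f = predict_mu(post_f, test, b_hat=b_hat)
        sel = np.isin(pats, held)
        rows_pred[sel] = mu_f
    cv_report = nrmse(rows_pred, y, pats, resp, mask, variant="cv")
    return in_report, cv_report


def compare_variants(cohort, variants=("two_level", "single_level",
                                       "separate_univariate"),
                     sampler=None):
    """Fit each model variant on the same cohort and score in-sample NRMSE;
    returns (summary table with per-response columns, dict of reports)."""
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    sampler = sampler or SamplerConfig()
    reports, rows = {}, []
    for v in variants:
        spec = v if isinstance(v, ModelSpec) else ModelSpec(variant=v)
        label = spec.variant
        post = fit(cohort, spec, sampler)
        resp = post.response_names
        idx = [cohort.response_names.index(r) for r in resp]
        mu = predict_mu(post, cohort)
        rep = nrmse(mu, cohort.y_matrix()[:, idx],
                    cohort.df["patient"].to_numpy(), resp,
                    cohort.mask()[:, idx], variant=label)
        reports[label] = rep
        row = {"variant": label, "overall": rep.overall}
        row.update(rep.per_response().to_dict())
        rows.append(row)
    return pd.DataFrame(rows), reports
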