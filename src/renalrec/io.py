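"""Persistence of fitted posteriors: columnar draws (npz) plus JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import QRDecorrelation, Standardizer
from .model import HierarchicalPosterior, ModelSpec

__all__ = ["save_posterior", "load_posterior"]


def save_posterior(post: HierarchicalPosterior, path):
    path = Path(path)
    np.savez_compressed(path, **post.draws)
    meta = {
        "spec": {"variant": post.spec.variant, "shift_c": post.spec.shift_c,
                 "intercept": post.spec.intercept,
                 "b_corr_within_only": post.spec.b_corr_within_only,
                 "scale_binary": post.spec.scale_binary,
                 "responses": post.spec.responses, "priors": post.spec.priors},
        "shift_c": post.shift_c,
        "seed": post.seed,
        "warnings": post.warnings,
        "patients": post.patients.tolist(),
        "treat_of_patient": post.treat_of_patient.tolist(),
        "treat_labels": post.treat_labels.tolist(),
        "predictor_names": post.predictor_names,
        "response_names": post.response_names,
        "standardizer": {"center": post.standardizer.center.tolist(),
                         "scale": post.standardizer.scale.tolist(),
                         "binary": post.standardizer.binary.tolist()},
        "qr": {"R_star": post.qr.R_star.tolist(), "n": post.qr.n},
        "diagnostics": post.diagnostics.to_dict(orient="list"),
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def load_posterior(path) -> HierarchicalPosterior:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        draws = {k: z[k] for k in z.files}
    with open(str(path) + ".meta.json") as fh:
        meta = json.load(fh)
    std = Standardizer.__new__(Standardizer)
    std.center = np.asarray(meta["standardizer"]["center"])
    std.scale = np.asarray(meta["standardizer"]["scale"])
    std.binary = np.asarray(meta["standardizer"]["binary"], bool)
    R_star = np.asarray(meta["qr"]["R_star"])
    from scipy.linalg import solve_triangular
    qr = QRDecorrelation(Q_star=None, R_star=R_star,
                         R_star_inv=solve_triangular(R_star,
                                                     np.eye(len(R_star))),
                         n=meta["qr"]["n"])
    spec = ModelSpec(**meta["spec"])
    return HierarchicalPosterior(
        draws=draws, diagnostics=pd.DataFrame(meta["diagnostics"]),
        spec=spec, shift_c=meta["shift_c"], standardizer=std, qr=qr,
        patients=np.asarray(meta["patients"]),
        treat_of_patient=np.asarray(meta["treat_of_patient"]),
        treat_labels=np.asarray(meta["treat_labels"]),
        predictor_names=meta["predictor_names"],
        response_names=meta["response_names"],
        seed=meta["seed"], warnings=meta["warnings"], sampler_stats=[])
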