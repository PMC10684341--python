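"""Brain-body allometry: phylogenetic regression and relative brain size.

Brain mass scales allometrically with body size, so comparative questions
about brains must first remove the body-size trend.  This module fits a
log-log phylogenetic generalized least squares (PGLS) regression of brain
mass on intertegular span with Pagel's lambda estimated by maximum
likelihood, and defines *relative brain size* as the residuals of that fit:
positive values mark species with larger brains than their body size
predicts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gls import SingularDesignError, gls_ml, profile_lambda
from .phylo import CovMatrix

__all__ = [
    "AllometryFit",
    "species_means",
    "fit_pgls",
    "relative_brain_size",
    "SingularDesignError",
]

SPECIMEN_COLUMNS = ("species", "brain_mg", "itd_mm")


@dataclass
class AllometryFit:
    """Maximum-likelihood PGLS fit of log brain mass on log body size.

    ``residuals`` (observed minus fitted log brain mass, in species order)
    are the relative brain sizes consumed downstream.  ``r2`` is the GLS
    variance-explained under the fitted covariance ``V(lambda_hat)``.
    """

    intercept: float
    slope: float
    lambda_hat: float
    sigma2: float
    r2: float
    loglik: float
    residuals: pd.Series
    n_species: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "lambda_hat": self.lambda_hat,
            "sigma2": self.sigma2,
            "r2": self.r2,
            "loglik": self.loglik,
            "n_species": self.n_species,
            "residuals": {k: float(v) for k, v in self.residuals.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def species_means(specimens: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a specimen table to species-level mean log traits.

    Measurements are log-transformed (natural log) per specimen and then
    averaged within species.  Returns a frame indexed by species with
    columns ``log_brain``, ``log_body`` and ``n_specimens`` (plus ``region``
    when present and unique per species).
    """
    missing = [c for c in SPECIMEN_COLUMNS if c not in specimens.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    for col in ("brain_mg", "itd_mm"):
        vals = pd.to_numeric(specimens[col], errors="raise")
        bad = specimens.index[~(vals > 0)]
        if len(bad):
            raise ValueError(
                f"non-positive {col} in specimen record(s) {list(bad[:5])}"
            )
    if (specimens["species"].astype(str).str.strip() == "").any():
        raise ValueError("empty species label in specimen table")
    df = specimens.assign(
        log_brain=np.log(specimens["brain_mg"].astype(float)),
        log_body=np.log(specimens["itd_mm"].astype(float)),
    )
    out = df.groupby("species").agg(
        log_brain=("log_brain", "mean"),
        log_body=("log_body", "mean"),
        n_specimens=("log_brain", "size"),
    )
    if "region" in df.columns:
        region = df.groupby("species")["region"].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else "both"
        )
        out["region"] = region
    out.index.name = "species"
    return out


def fit_pgls(traits: pd.DataFrame, V: CovMatrix) -> AllometryFit:
    """Fit log_brain ~ log_body by PGLS with ML-estimated Pagel's lambda.

    The residual covariance is ``sigma2 * V(lambda)`` with the off-diagonal
    of ``V`` scaled by lambda; lambda is profiled on [0, 1] and the
    coefficients solve the GLS normal equations at the optimum.
    """
    if len(traits) < 4:
        raise ValueError(f"PGLS needs >= 4 species, got {len(traits)}")
    species = list(traits.index)
    Vo = V.reorder(species)
    y = traits["log_brain"].to_numpy(dtype=float)
    x = traits["log_body"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise SingularDesignError("log_body is constant across species")
    X = np.column_stack([np.ones_like(x), x])
    lam_hat, ll_hat = profile_lambda(y, X, Vo.values)
    beta, sigma2, loglik, et = gls_ml(y, X, Vo.values, lam_hat)
    # weighted total SS from the intercept-only GLS model under the same V(lam)
    _, _, _, e0t = gls_ml(y, np.ones((len(y), 1)), Vo.values, lam_hat)
    wrss = float(et @ et)
    wtss = float(e0t @ e0t)
    r2 = 1.0 if wtss == 0 else 1.0 - wrss / wtss
    residuals = pd.Series(y - X @ beta, index=pd.Index(species, name="species"))
    return AllometryFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        lambda_hat=lam_hat,
        sigma2=float(sigma2),
        r2=float(np.clip(r2, 0.0, 1.0)),
        loglik=float(loglik),
        residuals=residuals,
        n_species=len(species),
    )


def relative_brain_size(fit: AllometryFit) -> pd.DataFrame:
    """Relative-brain-size score table from a PGLS fit.

    The score is the PGLS residual; rank 1 marks the species with the
    largest brain relative to its body size.
    """
    scores = fit.residuals
    rank = scores.rank(ascending=False, method="min").astype(int)
    return pd.DataFrame(
        {"residual": scores, "rank": rank},
        index=scores.index,
    ).sort_values("rank")
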