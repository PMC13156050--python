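"""Partial least squares correlation (PLSC) between thickness design and
symptom scores, with permutation and bootstrap inference.

The design matrix X holds [region thickness, age, thickness x age] per
patient, the behaviour matrix Y the PANSS item and factor scores; both are
column-standardised.  The cross-block matrix R = X'Y / (n - 1) is
decomposed by SVD, R = U S V'; each singular triplet is a latent variable
(LV) pairing a design salience (column of U) with a symptom salience
(column of V).  Permutation of Y rows yields p-values per LV; bootstrap
resampling of patients yields bootstrap ratios (BSR = salience / bootstrap
SE, |BSR| > 2 significant); behaviour scores are Y U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moderation import (
    JNSolution,
    ModerationFit,
    bh_fdr,
    fit_moderation,
    jn_boundaries,
)

__all__ = [
    "PLSCInputs",
    "PLSCModel",
    "build_inputs",
    "fit",
    "permutation_test",
    "bootstrap_ratios",
    "behavior_scores",
    "symptom_jn",
    "fdr_across_regions",
]


@dataclass
class PLSCInputs:
    """Row-aligned, column-standardised design and symptom matrices."""

    X: pd.DataFrame  # n x 3: thickness, age, interaction (z-scored)
    Y: pd.DataFrame  # n x items+factors (z-scored unless z_symptoms=False)
    n: int
    kept: np.ndarray  # positions of the retained rows in the input tables


@dataclass
class PLSCModel:
    """Point estimate of the PLSC decomposition (inference added separately)."""

    R: pd.DataFrame
    U: np.ndarray  # design saliences, columns = LVs
    S: np.ndarray  # singular values, non-increasing
    V: np.ndarray  # symptom saliences
    x_names: list[str]
    y_names: list[str]

    @property
    def n_lv(self) -> int:
        return len(self.S)


def _z(col: np.ndarray) -> np.ndarray:
    return (col - col.mean()) / col.std(ddof=1)


def build_inputs(
    region_thickness,
    age,
    symptoms: pd.DataFrame,
    z_symptoms: bool = True,
) -> PLSCInputs:
    """Assemble aligned PLSC inputs, dropping incomplete rows.

    The interaction column is the product of the standardised thickness and
    age columns, re-standardised; zero-variance symptom columns are
    excluded with a warning.  Raises if fewer than 10 complete rows remain.
    """
    thick = np.asarray(region_thickness, dtype=float)
    a = np.asarray(age, dtype=float)
    Y = symptoms.select_dtypes(include=[np.number]).copy()
    ok = np.isfinite(thick) & np.isfinite(a) & np.isfinite(np.asarray(Y)).all(axis=1)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} incomplete patient rows")
    kept = np.flatnonzero(ok)
    thick, a, Y = thick[ok], a[ok], Y.loc[ok]
    if len(thick) < 10:
        raise ValueError(f"need at least 10 complete rows, got {len(thick)}")
    keep = [c for c in Y.columns if Y[c].std(ddof=1) > 0]
    dropped = set(Y.columns) - set(keep)
    if dropped:
        warnings.warn(f"excluding zero-variance symptom columns: {sorted(dropped)}")
    Y = Y[keep]
    if thick.std(ddof=1) == 0:
        raise ValueError("region thickness has zero variance")
    zt, za = _z(thick), _z(a)
    X = pd.DataFrame(
        {"thickness": zt, "age": za, "thickness:age": _z(zt * za)}
    ).reset_index(drop=True)
    Yv = Y.reset_index(drop=True)
    if z_symptoms:
        Yv = Yv.apply(lambda c: _z(c.to_numpy()), axis=0)
    return PLSCInputs(X=X, Y=Yv, n=len(X), kept=kept)


def _svd_fixed_sign(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, k])), k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    return U, S, V


def fit(inputs: PLSCInputs) -> PLSCModel:
    """SVD of the cross-block matrix R = X'Y / (n - 1).

    The sign of each LV is fixed by making the largest-magnitude element of
    its design salience positive.
    """
    Xv = np.asarray(inputs.X, dtype=float)
    Yv = np.asarray(inputs.Y, dtype=float)
    R = Xv.T @ Yv / (inputs.n - 1)
    U, S, V = _svd_fixed_sign(R)
    return PLSCModel(
        R=pd.DataFrame(R, index=inputs.X.columns, columns=inputs.Y.columns),
        U=U,
        S=S,
        V=V,
        x_names=list(inputs.X.columns),
        y_names=list(inputs.Y.columns),
    )


def permutation_test(
    inputs: PLSCInputs,
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    collective: bool = False,
) -> np.ndarray:
    """Permutation p-value per latent variable.

    Rows of Y are permuted and the model refit; for LV k the p-value is
    (1 + #{S_k^perm >= S_k^obs}) / (1 + n_perm).  With ``collective=True``
    every permuted LV's singular value is compared against the largest
    permuted one (a maximum-statistic null), the stricter reading of a
    collective null distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    Xv = np.asarray(inputs.X, dtype=float)
    Yv = np.asarray(inputs.Y, dtype=float)
    S_obs = np.linalg.svd(Xv.T @ Yv / (inputs.n - 1), compute_uv=False)
    count = np.zeros_like(S_obs)
    for _ in range(n_perm):
        perm = rng.permutation(inputs.n)
        S_p = np.linalg.svd(Xv.T @ Yv[perm] / (inputs.n - 1), compute_uv=False)
        if collective:
            count += S_p.max() >= S_obs
        else:
            count += S_p >= S_obs
    return (1.0 + count) / (1.0 + n_perm)


def bootstrap_ratios(
    inputs: PLSCInputs,
    n_boot: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Bootstrap ratios for design (U) and symptom (V) saliences.

    Patients are resampled with replacement; each resample is re-standardised
    and refit, and its saliences are sign-aligned to the observed ones per
    LV.  BSR = observed salience / bootstrap SE; |BSR| > 2 is conventionally
    treated as significant.  Degenerate resamples (a constant column) are
    redrawn, with a warning carrying the count.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    Xv = np.asarray(inputs.X, dtype=float)
    Yv = np.asarray(inputs.Y, dtype=float)
    model = fit(inputs)
    U_obs, V_obs = model.U, model.V
    u_samples = np.empty((n_boot,) + U_obs.shape)
    v_samples = np.empty((n_boot,) + V_obs.shape)
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, inputs.n, inputs.n)
        Xb, Yb = Xv[idx], Yv[idx]
        sx, sy = Xb.std(axis=0, ddof=1), Yb.std(axis=0, ddof=1)
        if (sx == 0).any() or (sy == 0).any():
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        Xb = (Xb - Xb.mean(axis=0)) / sx
        Yb = (Yb - Yb.mean(axis=0)) / sy
        Ub, Sb, Vb = _svd_fixed_sign(Xb.T @ Yb / (inputs.n - 1))
        flip = np.sign((Ub * U_obs).sum(axis=0))
        flip[flip == 0] = 1.0
        u_samples[b] = Ub * flip
        v_samples[b] = Vb * flip
        b += 1
    if redraws:
        warnings.warn(f"redrew {redraws} degenerate bootstrap resamples")
    u_se = u_samples.std(axis=0, ddof=1)
    v_se = v_samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_u = np.where(u_se > 0, U_obs / u_se, np.inf)
        bsr_v = np.where(v_se > 0, V_obs / v_se, np.inf)
    return {
        "bsr_u": bsr_u,
        "bsr_v": bsr_v,
        "se_u": u_se,
        "se_v": v_se,
        "significant_u": np.abs(bsr_u) > 2,
        "significant_v": np.abs(bsr_v) > 2,
    }


def behavior_scores(Y, U) -> np.ndarray:
    """Project symptom rows onto the symptom-side saliences: scores = Y U."""
    Yv = np.asarray(Y, dtype=float)
    Uv = np.asarray(U, dtype=float)
    if Yv.shape[1] != Uv.shape[0]:
        raise ValueError(
            f"shape mismatch: Y has {Yv.shape[1]} columns, U has {Uv.shape[0]} rows"
        )
    return Yv @ Uv


def symptom_jn(
    scores,
    region_thickness,
    age,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    moderator_range: tuple[float, float] | None = None,
) -> tuple[ModerationFit, JNSolution]:
    """Johnson-Neyman follow-up: behaviour score ~ thickness x age.

    Confirms the latent relationship by moderation of the (continuous)
    thickness effect on the behaviour score by age; the sensitivity variant
    passes illness duration, age of onset, sex and education as covariates.
    """
    a = np.asarray(age, dtype=float)
    if moderator_range is None:
        moderator_range = (float(a.min()), float(a.max()))
    mfit = fit_moderation(
        scores,
        region_thickness,
        a,
        covariates=covariates,
        predictor_name="thickness",
        moderator_name="age",
    )
    return mfit, jn_boundaries(mfit, alpha=alpha, moderator_range=moderator_range)


def fdr_across_regions(p_values) -> np.ndarray:
    """BH correction across the four region-level PLSC analyses."""
    p = np.asarray(p_values, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"expected exactly 4 region-level p-values, got {p.shape}")
    return bh_fdr(p)
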