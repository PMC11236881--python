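"""Prediction for untested locations and leave-one-location-out validation.

A new location has no data and no location BLUP, so its genotype values are
predicted from the genotype main effects plus, for models with synthetic
covariates, the fixed and random regression on the new location's SC values:

    z_i = mu + a_i + sum_q t_q (beta_q + b_iq)                (main_effect)

For covariance structures that let part of the genotype main effect be
absorbed into the interaction (notably factor-analytic ones), the average of
the genotype's interaction BLUPs over the training locations can be added:

    z_i += mean_m s_im                        (main_plus_avg_interaction)

Model accuracy is scored by the mean squared error of predicted differences
(MSEPD) over all ordered genotype pairs and locations,

    MSEPD = sum_m sum_i sum_{i' != i} [(ybar_im - ybar_i'm)
                                        - (z_im - z_i'm)]^2 / (M I (I-1)),

and by the Spearman rank correlation between adjusted and predicted means,
computed per location and averaged.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    AMatrix,
    CVResult,
    ECTable,
    FitResult,
    MeanSet,
    ModelSpec,
    PredictionSet,
    stack_means,
)
from .stage1 import ConvergenceError, FitControls
from . import pls as _pls
from . import stage2 as _stage2

log = logging.getLogger(__name__)


def predict_new_location(fit: FitResult, location: str = "new",
                         sc_new: Optional[np.ndarray] = None,
                         mode: Optional[str] = None) -> PredictionSet:
    """Predict genotype values for a location absent from the training data.

    ``sc_new`` holds the new location's synthetic covariate values (required
    iff the fitted model regresses on SCs). The unseen location's own BLUP
    is zero by construction.
    """
    mode = mode or fit.spec.prediction_mode
    if mode not in ("main_effect", "main_plus_avg_interaction"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    q = fit.spec.n_sc
    if q > 0:
        if sc_new is None:
            raise ValueError("model uses synthetic covariates; sc_new required")
        t = np.asarray(sc_new, dtype=float).ravel()
        if t.size < q:
            raise ValueError(f"expected {q} SC values, got {t.size}")
        t = t[:q]
    else:
        t = np.zeros(0)
    z = fit.mu_hat + fit.blup_a.copy()
    for k in range(q):
        z = z + t[k] * (fit.beta_hat[k] + fit.blup_b[:, k])
    if mode == "main_plus_avg_interaction":
        if fit.blup_s.size == 0:
            raise ValueError("no interaction BLUPs available for "
                             "main_plus_avg_interaction prediction")
        z = z + fit.blup_s.mean(axis=0)
    return PredictionSet(location=location, genotypes=list(fit.genotypes),
                         z=np.asarray(z, dtype=float), mode=mode)


def _paired_arrays(observed: MeanSet, predicted: PredictionSet
                   ) -> tuple[np.ndarray, np.ndarray]:
    if list(observed.genotypes) != list(predicted.genotypes):
        obs, pred = set(observed.genotypes), set(predicted.genotypes)
        raise ValueError(
            f"genotype sets differ for location {observed.location!r}: "
            f"{sorted(obs ^ pred)[:5]} not shared")
    return observed.means, predicted.z


def msepd(observed: Sequence[MeanSet], predicted: Sequence[PredictionSet]) -> float:
    """Mean squared error of predicted genotype differences (t^2/ha^2).

    Exact evaluation over all ordered pairs i != i' and all locations. For
    each location the pair sum reduces to 2*(I*sum(d^2) - (sum d)^2) with
    d = observed - predicted, which makes the statistic invariant to any
    per-location additive shift of the predictions.
    """
    pred_by_loc = {p.location: p for p in predicted}
    total = 0.0
    I_ref: Optional[int] = None
    for ms in observed:
        if ms.location not in pred_by_loc:
            raise ValueError(f"no predictions for location {ms.location!r}")
        ybar, z = _paired_arrays(ms, pred_by_loc[ms.location])
        I = ybar.size
        if I_ref is None:
            I_ref = I
        elif I != I_ref:
            raise ValueError("genotype counts differ between locations")
        d = ybar - z
        total += 2.0 * (I * float(d @ d) - float(d.sum()) ** 2)
    M = len(list(observed))
    if I_ref is None or I_ref < 2:
        raise ValueError("need at least 2 genotypes for MSEPD")
    return total / (M * I_ref * (I_ref - 1))


def spearman_by_location(observed: Sequence[MeanSet],
                         predicted: Sequence[PredictionSet]
                         ) -> tuple[list[tuple[str, float]], float, float]:
    """Per-location Spearman rho (average ranks for ties), mean and SE.

    SE is the standard deviation of the per-location correlations divided by
    sqrt(M). Locations with a constant prediction or observation vector have
    undefined rho; they are recorded as NaN and excluded from the mean with
    a warning.
    """
    pred_by_loc = {p.location: p for p in predicted}
    per_loc: list[tuple[str, float]] = []
    for ms in observed:
        ybar, z = _paired_arrays(ms, pred_by_loc[ms.location])
        if ybar.size < 3:
            raise ValueError("need at least 3 genotypes for rank correlation")
        if np.ptp(z) == 0 or np.ptp(ybar) == 0:
            log.warning("constant vector at location %r: rho undefined, "
                        "excluded from the average", ms.location)
            per_loc.append((ms.location, float("nan")))
            continue
        rho = stats.spearmanr(ybar, z).statistic
        per_loc.append((ms.location, float(rho)))
    vals = np.array([r for _, r in per_loc if np.isfinite(r)])
    if vals.size == 0:
        return per_loc, float("nan"), float("nan")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return per_loc, mean, se


def leave_one_location_out(mean_sets: Sequence[MeanSet], spec: ModelSpec,
                           A: Optional[AMatrix] = None,
                           ec: Optional[ECTable] = None,
                           fa_order_path: bool = False,
                           controls: Optional[FitControls] = None,
                           model_id: str = "custom",
                           strict: bool = False) -> CVResult:
    """Leave-one-location-out cross-validation of one Stage II model.

    For each location in turn: the held-out mean set is removed, the
    synthetic covariates (if any) are re-extracted on the training locations
    only (standardization statistics and PLS fit never see the held-out
    location; its SC values come from projection), the model is refit by
    REML, and the held-out genotypes are predicted. Scores aggregate over
    all folds. Non-convergent folds are listed in ``failed_folds`` and
    excluded; with ``strict=True`` they raise instead.
    """
    mean_sets = sorted(mean_sets, key=lambda m: m.location)
    M = len(mean_sets)
    if M < 3:
        raise ValueError("leave-one-location-out needs at least 3 locations")
    if spec.n_sc > 0 and ec is None:
        raise ValueError("spec uses synthetic covariates but no EC table given")
    predictions: list[PredictionSet] = []
    scored_obs: list[MeanSet] = []
    failed: list[str] = []
    for held in list(range(M)):
        held_loc = mean_sets[held].location
        training = [m for k, m in enumerate(mean_sets) if k != held]
        try:
            stacked = stack_means(training, intersect=True)
            sc_frame = None
            sc_new = None
            if spec.n_sc > 0:
                model, z = _pls.extract_sc(training, ec, n_components=spec.n_sc,
                                           reference_locations=[m.location
                                                                for m in training])
                sc_frame = model.scores_frame()
                sc_new = _pls.project_location(model, z.row(held_loc))
            if spec.pi_structure == "fa" and fa_order_path:
                fit = _stage2.fit_fa_order_path(stacked, spec, A=A, sc=sc_frame,
                                                controls=controls)
            else:
                mm = _stage2.build_model(stacked, spec, A=A, sc=sc_frame)
                fit = _stage2.reml_fit(mm, controls=controls)
            pred = predict_new_location(fit, location=held_loc, sc_new=sc_new,
                                        mode=spec.prediction_mode)
        except (ConvergenceError, np.linalg.LinAlgError) as e:
            if strict:
                raise
            log.warning("fold %r failed: %s", held_loc, e)
            failed.append(held_loc)
            continue
        obs = mean_sets[held].subset([g for g in pred.genotypes
                                      if g in mean_sets[held].genotypes])
        if list(obs.genotypes) != list(pred.genotypes):
            keep = [g for g in pred.genotypes if g in set(obs.genotypes)]
            sel = [pred.genotypes.index(g) for g in keep]
            pred = PredictionSet(pred.location, keep, pred.z[sel], pred.mode)
        predictions.append(pred)
        scored_obs.append(obs)
    if not predictions:
        raise ConvergenceError("all CV folds failed", [])
    if failed:
        log.warning("MSEPD computed over %d converged folds; failed: %s",
                    len(predictions), failed)
    value = msepd(scored_obs, predictions)
    per_loc, mean_rho, se_rho = spearman_by_location(scored_obs, predictions)
    return CVResult(model_id=model_id, spec=spec, per_location_rho=per_loc,
                    msepd=value, mean_rho=mean_rho, se_rho=se_rho,
                    predictions=predictions, failed_folds=failed)


def cross_validate_model(mean_sets: Sequence[MeanSet], model_id: str,
                         n_sc: int = 1, fa_order: Optional[int] = None,
                         prediction_mode: str = "main_effect",
                         A: Optional[AMatrix] = None,
                         ec: Optional[ECTable] = None,
                         controls: Optional[FitControls] = None,
                         strict: bool = False) -> CVResult:
    """Leave-one-location-out CV for a catalogue model (M1-M12)."""
    spec = ModelSpec.from_id(model_id, n_sc=n_sc,
                             fa_order=fa_order if fa_order else 1,
                             prediction_mode=prediction_mode)
    return leave_one_location_out(
        mean_sets, spec, A=A, ec=ec,
        fa_order_path=(spec.pi_structure == "fa" and fa_order is None),
        controls=controls, model_id=model_id, strict=strict)
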