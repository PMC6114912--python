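"""Naive Bayes MSI classification from deletion frequency and allelic bias.

Each marker i contributes an observation O_i = (D_i, B_i): D_i indicates
that the sample's deletion-read frequency exceeds the marker threshold
t_i, and B_i indicates significant allelic bias (Fisher's exact p below
alpha at the best heterozygous flanking SNP).  Assuming conditional
independence across markers,

    S = log10 p(MSI|O)/p(MSS|O)
      = log10 p(MSI)/p(MSS) + sum_i log10 p(O_i|MSI)/p(O_i|MSS)

and a sample is called MSI-H iff S > 0.  The bias factor is included only
when D_i = 1 (below the threshold there is insufficient evidence for a
repeat mutation, so bias is not meaningful), at least one flanking SNP is
heterozygous, and the bias parameters could be estimated for both
classes.  Conditional probabilities are estimated from labelled training
counts with Laplace smoothing so every factor is finite.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

from .datamodel import (
    MSI_H,
    MSS,
    NOT_ASSESSABLE,
    ClassificationResult,
    MarkerContribution,
    MarkerDefinition,
    MarkerObservation,
    MarkerParameters,
    SampleRecord,
    TrainedModel,
    ValidationError,
)
from .extraction import bias_table
from .stats import empirical_threshold, fisher_exact_two_sided, wilson_interval

logger = logging.getLogger(__name__)

#: fraction of MSS training samples required below each marker threshold
THRESHOLD_COVERAGE = 0.95


def min_bias_p(obs: MarkerObservation) -> tuple[str, float] | None:
    """Best (lowest Fisher p) heterozygous flanking SNP, or None.

    When several SNPs are heterozygous the one with the lowest p-value is
    used; ties are broken by panel order.
    """
    best: tuple[str, float] | None = None
    for snp_id in obs.heterozygous_snps():
        p = fisher_exact_two_sided(bias_table(obs, snp_id))
        if best is None or p < best[1]:
            best = (snp_id, p)
    return best


def _smoothed(k: int, n: int, pseudocount: float) -> float:
    return (k + pseudocount) / (n + 2 * pseudocount)


def _exceedance(
    samples: Sequence[SampleRecord], marker_id: str, threshold: float
) -> tuple[int, int]:
    k = n = 0
    for sample in samples:
        obs = sample.observations.get(marker_id)
        if obs is None or not obs.usable:
            continue
        n += 1
        if obs.histogram.deletion_fraction > threshold:
            k += 1
    return k, n


def _bias_counts(
    samples: Sequence[SampleRecord],
    marker_id: str,
    threshold: float,
    bias_alpha: float,
) -> tuple[int, int]:
    """Significant-bias counts among above-threshold heterozygous samples."""
    k = n = 0
    for sample in samples:
        obs = sample.observations.get(marker_id)
        if obs is None or not obs.usable:
            continue
        if obs.histogram.deletion_fraction <= threshold:
            continue
        best = min_bias_p(obs)
        if best is None:
            continue
        n += 1
        if best[1] < bias_alpha:
            k += 1
    return k, n


def train(
    cohort: Iterable[SampleRecord],
    panel: Iterable[MarkerDefinition],
    priors: tuple[float, float] = (0.15, 0.85),
    bias_alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> TrainedModel:
    """Estimate per-marker thresholds and conditional probabilities.

    For every marker: the threshold t_i is the nearest-rank 95% quantile
    of the deletion fractions of usable MSS training samples;
    p(D=1|class) comes from exact exceedance counts, and p(B=1|D=1,class)
    from the subset of above-threshold samples heterozygous at a flanking
    SNP, both Laplace-smoothed.  A marker with no usable MSS sample is
    dropped from the model with a warning record.
    """
    cohort = list(cohort)
    panel = list(panel)
    msi = [s for s in cohort if s.label == MSI_H]
    mss = [s for s in cohort if s.label == MSS]
    if not msi or not mss:
        raise ValidationError(
            f"training requires both classes; got {len(msi)} MSI-H and "
            f"{len(mss)} MSS samples"
        )
    prior_msi, prior_mss = priors
    markers: dict[str, MarkerParameters] = {}
    dropped: list[str] = []
    for marker in panel:
        mid = marker.marker_id
        mss_fracs = [
            obs.histogram.deletion_fraction
            for s in mss
            if (obs := s.observations.get(mid)) is not None and obs.usable
        ]
        if not mss_fracs:
            logger.warning(
                "marker %s: no usable MSS training sample; dropped", mid
            )
            dropped.append(mid)
            continue
        threshold = empirical_threshold(mss_fracs, THRESHOLD_COVERAGE)
        k_d_msi, n_d_msi = _exceedance(msi, mid, threshold)
        k_d_mss, n_d_mss = _exceedance(mss, mid, threshold)
        k_b_msi, n_b_msi = _bias_counts(msi, mid, threshold, bias_alpha)
        k_b_mss, n_b_mss = _bias_counts(mss, mid, threshold, bias_alpha)
        markers[mid] = MarkerParameters(
            marker_id=mid,
            threshold=threshold,
            p_d_msi=_smoothed(k_d_msi, n_d_msi, pseudocount),
            p_d_mss=_smoothed(k_d_mss, n_d_mss, pseudocount),
            p_b_msi=(
                _smoothed(k_b_msi, n_b_msi, pseudocount) if n_b_msi else None
            ),
            p_b_mss=(
                _smoothed(k_b_mss, n_b_mss, pseudocount) if n_b_mss else None
            ),
            counts={
                "d_msi": (k_d_msi, n_d_msi),
                "d_mss": (k_d_mss, n_d_mss),
                "b_msi": (k_b_msi, n_b_msi) if n_b_msi else None,
                "b_mss": (k_b_mss, n_b_mss) if n_b_mss else None,
            },
        )
    model = TrainedModel(
        markers=markers,
        prior_msi=prior_msi,
        prior_mss=prior_mss,
        bias_alpha=bias_alpha,
        pseudocount=pseudocount,
        provenance={
            "n_msi": len(msi),
            "n_mss": len(mss),
            "dropped_markers": dropped,
        },
    )
    model.validate()
    return model


def marker_factor(
    obs: MarkerObservation | None,
    params: MarkerParameters,
    bias_alpha: float,
    use_bias: bool = True,
) -> MarkerContribution:
    """Log10 likelihood-ratio contribution of one marker.

    The deletion-frequency term is always present for a usable
    observation; the bias term is added only when D = 1, a heterozygous
    flanking SNP exists, and both class bias parameters are available.
    """
    mid = params.marker_id
    if obs is None:
        return MarkerContribution(mid, used=False, note="no observation")
    if not obs.usable:
        return MarkerContribution(
            mid,
            used=False,
            note=f"insufficient depth ({obs.histogram.total} read pairs)",
        )
    d = obs.histogram.deletion_fraction > params.threshold
    if d:
        factor = math.log10(params.p_d_msi / params.p_d_mss)
    else:
        factor = math.log10((1 - params.p_d_msi) / (1 - params.p_d_mss))
    b: bool | None = None
    snp_id: str | None = None
    bias_p: float | None = None
    note = ""
    if d and use_bias:
        best = min_bias_p(obs)
        if best is None:
            note = "no heterozygous flanking SNP"
        elif not params.bias_available:
            snp_id, bias_p = best
            note = "bias parameters unavailable"
        else:
            snp_id, bias_p = best
            b = bias_p < bias_alpha
            if b:
                factor += math.log10(params.p_b_msi / params.p_b_mss)
            else:
                factor += math.log10(
                    (1 - params.p_b_msi) / (1 - params.p_b_mss)
                )
    return MarkerContribution(
        mid, used=True, d=d, b=b, snp_id=snp_id, bias_p=bias_p,
        log10_factor=factor, note=note,
    )


def score_sample(
    sample: SampleRecord,
    model: TrainedModel,
    min_markers: int = 1,
    use_bias: bool = True,
) -> ClassificationResult:
    """Score one sample and call MSI-H (S > 0) or MSS (S <= 0).

    A score of exactly 0 is resolved conservatively to MSS.  When fewer
    than ``min_markers`` observations are usable the call is
    "not assessable"; with ``min_markers = 0`` an entirely uninformative
    sample scores the prior log-odds alone.
    """
    contributions = [
        marker_factor(
            sample.observations.get(mid), params, model.bias_alpha, use_bias
        )
        for mid, params in model.markers.items()
    ]
    used = [c for c in contributions if c.used]
    n_bias = sum(1 for c in used if c.b is not None)
    if len(used) < min_markers:
        return ClassificationResult(
            sample_id=sample.sample_id,
            score=None,
            call=NOT_ASSESSABLE,
            contributions=contributions,
            n_markers_used=len(used),
            n_bias_assessed=n_bias,
            reason=(
                f"only {len(used)} usable markers "
                f"(minimum {min_markers})"
            ),
        )
    score = model.log10_prior_odds + sum(c.log10_factor for c in used)
    return ClassificationResult(
        sample_id=sample.sample_id,
        score=score,
        call=MSI_H if score > 0 else MSS,
        contributions=contributions,
        n_markers_used=len(used),
        n_bias_assessed=n_bias,
    )


def classify_cohort(
    samples: Iterable[SampleRecord],
    model: TrainedModel,
    min_markers: int = 1,
    use_bias: bool = True,
) -> tuple[list[ClassificationResult], dict | None]:
    """Score every sample; summarise accuracy when labels are present.

    The summary reports sensitivity, specificity and concordance against
    the provided labels (MSI-H = positive class) with Wilson 95%
    intervals, over labelled samples with an assessable call.
    """
    samples = list(samples)
    results = [
        score_sample(s, model, min_markers=min_markers, use_bias=use_bias)
        for s in samples
    ]
    labelled = [
        (s, r)
        for s, r in zip(samples, results)
        if s.label in (MSI_H, MSS) and r.call != NOT_ASSESSABLE
    ]
    if not labelled:
        return results, None
    tp = sum(1 for s, r in labelled if s.label == MSI_H and r.call == MSI_H)
    fn = sum(1 for s, r in labelled if s.label == MSI_H and r.call == MSS)
    tn = sum(1 for s, r in labelled if s.label == MSS and r.call == MSS)
    fp = sum(1 for s, r in labelled if s.label == MSS and r.call == MSI_H)
    summary: dict = {
        "n": len(labelled),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "concordance": (tp + tn) / len(labelled),
    }
    if tp + fn:
        summary["sensitivity_ci"] = wilson_interval(tp, tp + fn)
    if tn + fp:
        summary["specificity_ci"] = wilson_interval(tn, tn + fp)
    return results, summary
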