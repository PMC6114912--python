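"""In-silico mixing of sample pairs for limit-of-detection analysis.

Reads from one MSI-H and one MSS sample are mixed at a fixed proportion:
per marker, the mixed relative frequencies over length deviations are the
proportion-weighted average of the two samples' frequencies, realised at
a target depth either deterministically (largest-remainder apportionment,
exact depth conservation) or as a seeded multinomial draw.  Each mixture
is then classified as if it were a new sample; sweeping a grid of
proportions over every (MSS, MSI-H) cross pair yields the detection curve.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import score_sample
from .datamodel import (
    MSI_H,
    LengthHistogram,
    MarkerObservation,
    SampleRecord,
    SnpObservation,
    TrainedModel,
    ValidationError,
)

DEFAULT_STEP = 0.025


def proportion_grid(step: float = DEFAULT_STEP) -> np.ndarray:
    """Inclusive grid of mixing proportions from 0 to 1."""
    if not 0.0 < step <= 1.0:
        raise ValidationError(f"step {step} outside (0, 1]")
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def cross_pairs(
    mss_cohort: Sequence[SampleRecord], msi_cohort: Sequence[SampleRecord]
) -> list[tuple[SampleRecord, SampleRecord]]:
    """All (MSS, MSI-H) sample pairings."""
    return list(itertools.product(mss_cohort, msi_cohort))


def largest_remainder(freqs: np.ndarray, n: int) -> np.ndarray:
    """Apportion n counts to frequencies, conserving the total exactly.

    Largest-remainder (Hamilton) rounding; ties broken by array order.
    """
    freqs = np.asarray(freqs, dtype=float)
    total = freqs.sum()
    if total <= 0:
        raise ValidationError("cannot apportion over zero total frequency")
    exact = freqs / total * n
    base = np.floor(exact).astype(np.int64)
    remainder = exact - base
    short = int(n - base.sum())
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    return base


def _mix_cells(
    cells_a: dict, total_a: int, cells_b: dict, total_b: int, prop_a: float
) -> dict:
    """Proportion-weighted mixture of two count dicts as frequencies."""
    keys = sorted(set(cells_a) | set(cells_b), key=repr)
    mixed = {}
    for key in keys:
        f = 0.0
        if total_a:
            f += prop_a * cells_a.get(key, 0) / total_a
        if total_b:
            f += (1.0 - prop_a) * cells_b.get(key, 0) / total_b
        mixed[key] = f
    return mixed


def _realise(
    freqs: dict, n: int, mode: str, rng: np.random.Generator | None
) -> dict:
    keys = list(freqs)
    values = np.array([freqs[k] for k in keys], dtype=float)
    if mode == "deterministic":
        counts = largest_remainder(values, n)
    elif mode == "stochastic":
        if rng is None:
            raise ValidationError("stochastic mixing requires a seed")
        counts = rng.multinomial(n, values / values.sum())
    else:
        raise ValidationError(f"unknown mixing mode {mode!r}")
    return {k: int(c) for k, c in zip(keys, counts) if c > 0}


def _target_depth(total_a: int, total_b: int, depth_rule: str) -> int:
    if depth_rule == "min":
        return min(total_a, total_b)
    if depth_rule == "sum":
        return total_a + total_b
    raise ValidationError(f"unknown depth rule {depth_rule!r}")


def mix_observations(
    msi_sample: SampleRecord,
    mss_sample: SampleRecord,
    prop_msi: float,
    mode: str = "deterministic",
    seed: int | None = None,
    depth_rule: str = "min",
) -> SampleRecord:
    """Mix two samples' reads at a fixed MSI-H proportion.

    Per common marker the target depth is the min (default) or sum of the
    two observed depths; marker and allele-stratified histograms are
    mixed on the same frequencies.  Heterozygosity is re-called on the
    mixed counts downstream, as for any other sample.
    """
    if not 0.0 <= prop_msi <= 1.0:
        raise ValidationError(f"prop_msi {prop_msi} outside [0, 1]")
    common = [
        mid
        for mid in msi_sample.observations
        if mid in mss_sample.observations
        and msi_sample.observations[mid].histogram.total > 0
        and mss_sample.observations[mid].histogram.total > 0
    ]
    if not common:
        raise ValidationError(
            f"samples {msi_sample.sample_id} and {mss_sample.sample_id} "
            f"share no observed marker"
        )
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    mixed_id = (
        f"{mss_sample.sample_id}+{msi_sample.sample_id}@{prop_msi:.3f}"
    )
    mixed = SampleRecord(mixed_id)
    for mid in common:
        obs_msi = msi_sample.observations[mid]
        obs_mss = mss_sample.observations[mid]
        n = _target_depth(
            obs_msi.histogram.total, obs_mss.histogram.total, depth_rule
        )
        freqs = _mix_cells(
            obs_msi.histogram.counts,
            obs_msi.histogram.total,
            obs_mss.histogram.counts,
            obs_mss.histogram.total,
            prop_msi,
        )
        obs = MarkerObservation(mid, LengthHistogram(_realise(freqs, n, mode, rng)))
        for snp_id in obs_msi.snp_observations.keys() | obs_mss.snp_observations.keys():
            cells_a: dict = {}
            total_a = 0
            if snp_id in obs_msi.snp_observations:
                for allele, h in obs_msi.snp_observations[snp_id].allele_histograms.items():
                    for dev, c in h.counts.items():
                        cells_a[(allele, dev)] = c
                        total_a += c
            cells_b: dict = {}
            total_b = 0
            if snp_id in obs_mss.snp_observations:
                for allele, h in obs_mss.snp_observations[snp_id].allele_histograms.items():
                    for dev, c in h.counts.items():
                        cells_b[(allele, dev)] = c
                        total_b += c
            n_snp = _target_depth(total_a, total_b, depth_rule)
            snp_obs = SnpObservation(snp_id)
            if n_snp > 0:
                joint = _mix_cells(cells_a, total_a, cells_b, total_b, prop_msi)
                realised = _realise(joint, n_snp, mode, rng)
                for (allele, dev), c in realised.items():
                    hist = snp_obs.allele_histograms.setdefault(
                        allele, LengthHistogram()
                    )
                    hist.add(dev, c)
            obs.snp_observations[snp_id] = snp_obs
        mixed.observations[mid] = obs
    return mixed


def lod_grid(
    msi_cohort: Sequence[SampleRecord],
    mss_cohort: Sequence[SampleRecord],
    model: TrainedModel,
    step: float = DEFAULT_STEP,
    mode: str = "deterministic",
    seed: int | None = None,
    depth_rule: str = "min",
    min_markers: int = 1,
) -> pd.DataFrame:
    """Detection curve over a grid of mixing proportions.

    Every (MSS, MSI-H) cross pair is mixed at every grid proportion and
    scored with the trained model.  Returns one row per proportion with
    the fraction of pairs called MSI-H.  ``prop_mss`` (= 1 - prop_msi) is
    included because detection curves are conventionally plotted against
    the stable-component proportion.
    """
    if not msi_cohort or not mss_cohort:
        raise ValidationError("lod_grid requires non-empty cohorts")
    model.validate()
    grid = proportion_grid(step)
    pairs = cross_pairs(mss_cohort, msi_cohort)
    seeds = None
    if mode == "stochastic":
        root = np.random.SeedSequence(seed)
        seeds = [
            s.generate_state(1)[0] % (2**31)
            for s in root.spawn(len(grid) * len(pairs))
        ]
    rows = []
    for gi, prop in enumerate(grid):
        n_called = 0
        for pi, (mss_sample, msi_sample) in enumerate(pairs):
            pair_seed = seeds[gi * len(pairs) + pi] if seeds else None
            mixture = mix_observations(
                msi_sample, mss_sample, float(prop),
                mode=mode, seed=pair_seed, depth_rule=depth_rule,
            )
            result = score_sample(mixture, model, min_markers=min_markers)
            if result.call == MSI_H:
                n_called += 1
        rows.append(
            {
                "prop_msi": float(prop),
                "prop_mss": float(1.0 - prop),
                "n_pairs": len(pairs),
                "n_called_msi": n_called,
                "call_fraction": n_called / len(pairs),
            }
        )
    return pd.DataFrame(rows)
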