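"""Seeded generators for two-channel array studies and survival cohorts.

The array generator emulates the statistical structure the pipeline
assumes: a 27-sample, 3-group design (9 TNBC, 9 Luminal A, 9 Luminal B by
default), thousands of probes with log-normal raw intensities (Gaussian on
the log2 scale), a spike-in block with fixed input amounts shared across
arrays, per-array multiplicative scale effects (which spike-in
normalization removes), a configurable fraction of truly differentially
methylated probes with log2 effects around 1.77 in a designated target
group, per-probe noise SD 1 on the log2 scale, and P/A QC flags with a
configurable absent rate.  Genomic categories are drawn with
exonic-majority weights (0.6/0.2/0.1/0.05/0.05).

The survival generator draws exponential event times whose hazard is
multiplied by a true hazard ratio for subjects whose latent expression lies
above the median, with independent uniform censoring tuned to a requested
censoring fraction.

One global seed drives everything; independent sub-streams are derived per
component so enlarging the probe panel does not perturb sample-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import CATEGORIES, ChannelMatrix, ProbeAnnotation

DEFAULT_GROUP_SIZES = {"TNBC": 9, "LuminalA": 9, "LuminalB": 9}
CATEGORY_WEIGHTS = (0.6, 0.2, 0.1, 0.05, 0.05)


class SimulationError(ValueError):
    pass


@dataclass
class SimulatedStudy:
    ip: ChannelMatrix
    sup: ChannelMatrix
    annotation: list[ProbeAnnotation]
    samples: pd.DataFrame
    truth: pd.DataFrame   # probe_id, is_dm, true_log2fc, sd
    spike_ids: list[str] = field(default_factory=list)


def simulate_array(
    n_probes: int = 2000,
    n_spike: int = 20,
    group_sizes: dict[str, int] | None = None,
    frac_dm: float = 0.05,
    effect_mean: float = 1.77,
    effect_sd: float = 0.25,
    noise_sd: float = 1.0,
    flag_absent_rate: float = 0.05,
    target_group: str | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Simulate a two-channel spike-in-normalized array study.

    Differentially methylated probes (a ``frac_dm`` fraction) receive a
    log2 effect of magnitude ~N(effect_mean, effect_sd) with random sign in
    the target group (first group by default), so a TNBC-vs-luminal
    contrast sees true hyper- and hypomethylation.  Raw intensities are
    2^(log2 value); each array gets a multiplicative scale factor applied
    to every probe including the spike-ins, which normalization cancels.
    """
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    if not 0 <= frac_dm <= 1:
        raise SimulationError("frac_dm must lie in [0, 1]")
    if any(n < 2 for n in group_sizes.values()):
        raise SimulationError("every group needs >= 2 samples")
    if n_spike < 2:
        raise SimulationError("need >= 2 spike-in probes")
    if not 0 <= flag_absent_rate < 1:
        raise SimulationError("flag_absent_rate must lie in [0, 1)")
    if noise_sd <= 0:
        raise SimulationError("noise_sd must be > 0")
    groups = list(group_sizes)
    target = target_group if target_group is not None else groups[0]
    if target not in group_sizes:
        raise SimulationError(f"unknown target group {target!r}")

    # independent sub-streams: probe-level truth, sample-level effects, noise
    root = np.random.SeedSequence(seed)
    rng_probe, rng_sample, rng_noise, rng_flags = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    sample_ids, group_labels = [], []
    for g in groups:
        for i in range(group_sizes[g]):
            sample_ids.append(f"{g}_{i + 1:02d}")
            group_labels.append(g)
    samples = pd.DataFrame({"sample_id": sample_ids, "group": group_labels})
    n_samples = len(sample_ids)
    is_target = np.array([g == target for g in group_labels])

    probe_ids = [f"circ_{i:05d}" for i in range(1, n_probes + 1)]
    spike_ids = [f"spike_{i:02d}" for i in range(1, n_spike + 1)]

    # probe-level truth
    baseline = rng_probe.normal(10.0, 1.5, size=n_probes)
    n_dm = int(round(frac_dm * n_probes))
    is_dm = np.zeros(n_probes, dtype=bool)
    if n_dm:
        is_dm[rng_probe.choice(n_probes, size=n_dm, replace=False)] = True
    magnitude = np.abs(rng_probe.normal(effect_mean, effect_sd, size=n_probes))
    sign = rng_probe.choice([-1.0, 1.0], size=n_probes)
    true_log2fc = np.where(is_dm, sign * magnitude, 0.0)
    # Sup channel offset governs the true modification stoichiometry and
    # varies smoothly across probes
    sup_offset = rng_probe.normal(0.0, 1.0, size=n_probes)
    categories = rng_probe.choice(CATEGORIES, size=n_probes, p=CATEGORY_WEIGHTS)
    chroms = rng_probe.choice([f"chr{i}" for i in range(1, 23)], size=n_probes)
    strands = rng_probe.choice(["+", "-"], size=n_probes)

    # per-array multiplicative scale (additive on log2), removed by spike-ins
    array_shift = rng_sample.normal(0.0, 0.3, size=n_samples)

    ip_log2 = (
        baseline[:, None]
        + np.where(is_target, 1.0, 0.0)[None, :] * true_log2fc[:, None]
        + rng_noise.normal(0.0, noise_sd, size=(n_probes, n_samples))
        + array_shift[None, :]
    )
    sup_log2 = (
        baseline[:, None]
        + sup_offset[:, None]
        + rng_noise.normal(0.0, noise_sd, size=(n_probes, n_samples))
        + array_shift[None, :]
    )

    # spike-in block: fixed input amounts, shared across arrays up to the
    # per-array scale and small technical noise
    spike_base = np.linspace(6.0, 12.0, n_spike)
    spike_log2 = (
        spike_base[:, None]
        + array_shift[None, :]
        + rng_noise.normal(0.0, 0.05, size=(n_spike, n_samples))
    )

    index = pd.Index(probe_ids + spike_ids, name="probe_id")
    ip_values = pd.DataFrame(
        np.exp2(np.vstack([ip_log2, spike_log2])), index=index, columns=sample_ids
    )
    sup_values = pd.DataFrame(
        np.exp2(np.vstack([sup_log2, spike_log2])), index=index, columns=sample_ids
    )

    flags = np.where(
        rng_flags.random((n_probes, n_samples)) < flag_absent_rate, "A", "P"
    )
    spike_flags = np.full((n_spike, n_samples), "P")
    qc = pd.DataFrame(np.vstack([flags, spike_flags]), index=index, columns=sample_ids)

    ip = ChannelMatrix(channel="IP_Cy5", values=ip_values, qc_flags=qc.copy())
    sup = ChannelMatrix(channel="Sup_Cy3", values=sup_values, qc_flags=qc.copy())

    annotation = [
        ProbeAnnotation(
            probe_id=pid,
            host_gene=f"GENE{i + 1:05d}",
            chromosome=chroms[i],
            strand=strands[i],
            category=categories[i],
            is_spike_in=False,
            start=1000 * (i + 1),
            end=1000 * (i + 1) + 500,
        )
        for i, pid in enumerate(probe_ids)
    ] + [
        ProbeAnnotation(
            probe_id=sid, host_gene="spike", chromosome="spike",
            strand="unknown", category=None, is_spike_in=True,
        )
        for sid in spike_ids
    ]

    truth = pd.DataFrame({
        "probe_id": probe_ids,
        "is_dm": is_dm,
        "true_log2fc": true_log2fc,
        "sd": noise_sd,
        "baseline": baseline,
    })
    return SimulatedStudy(
        ip=ip, sup=sup, annotation=annotation, samples=samples,
        truth=truth, spike_ids=spike_ids,
    )


def _uniform_censor_bound(rates: np.ndarray, censor_rate: float) -> float:
    """Upper bound u of Uniform(0, u) censoring achieving the requested
    expected censored fraction for a mix of exponential event rates."""

    def censored_fraction(u: float) -> float:
        # P(C < T) for C ~ U(0,u), T ~ Exp(rate): (1 - exp(-rate*u))/(rate*u)
        with np.errstate(over="ignore"):
            return float(np.mean((1 - np.exp(-rates * u)) / (rates * u)))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return optimize.brentq(lambda u: censored_fraction(u) - censor_rate, lo, hi)


def simulate_survival(
    n: int = 300,
    true_hr: float = 2.4,
    baseline_hazard: float = 1.0 / 1500.0,
    censor_rate: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a survival cohort with a median-split marker effect.

    Event times are exponential with hazard ``baseline_hazard`` (per day),
    multiplied by ``true_hr`` for subjects whose latent expression exceeds
    the cohort median.  Censoring is independent Uniform(0, u) with u tuned
    so the expected censored fraction is ``censor_rate``.
    """
    if n < 10:
        raise SimulationError("need n >= 10")
    if true_hr <= 0 or baseline_hazard <= 0:
        raise SimulationError("true_hr and baseline_hazard must be > 0")
    if not 0 <= censor_rate < 1:
        raise SimulationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expression = rng.normal(0.0, 1.0, size=n)
    high = expression > np.median(expression)
    rates = baseline_hazard * np.where(high, true_hr, 1.0)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        u = _uniform_censor_bound(rates, censor_rate)
        censor_times = rng.uniform(0.0, u, size=n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(n, dtype=int)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "time": np.maximum(time, 1e-9),
        "event": event,
        "expression": expression,
    })
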