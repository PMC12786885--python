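"""Spike-in normalization, m6A quantity, %Modified and QC-based retention.

Each array (sample) carries a shared block of exogenous spike-in probes of
known input amount.  Normalization subtracts, per array and per channel, the
arithmetic mean of the log2 spike-in intensities (i.e. the log2 of their
geometric mean) from every probe's log2 raw intensity:

    norm[probe, s] = log2(raw[probe, s]) - mean_{spike i}( log2(raw[i, s]) )

The "m6A quantity" of a probe is its normalized IP (Cy5) intensity.  The
modification stoichiometry is

    %Modified = IP / (IP + Sup)

computed on the normalized intensities; because normalized log2 values can
be negative (probe dimmer than the spike-in geometric mean), the printed
ratio can leave [0, 1] — such cells are clamped and flagged ``out_of_range``.
A ``linear`` scale variant (2^ip / (2^ip + 2^sup)) is available.

Probes are retained when they carry a Present or Marginal QC flag in at
least ``min_pm`` samples (default 4), counted across all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ChannelMatrix

PERCENT_MODIFIED_SCALES = ("log2_normalized", "linear")


class QuantificationError(ValueError):
    pass


@dataclass
class QuantificationResult:
    """Per probe x sample normalized intensities and derived quantities."""

    ip_norm: pd.DataFrame
    sup_norm: pd.DataFrame
    percent_modified: pd.DataFrame
    out_of_range: pd.DataFrame    # bool; %Modified fell outside [0,1] before clamping
    retained: pd.Series           # bool per probe (spike-ins excluded)
    scale: str = "log2_normalized"

    @property
    def m6a_quantity(self) -> pd.DataFrame:
        """The m6A quantity is, by definition, the normalized IP intensity."""
        return self.ip_norm

    def to_table(self) -> pd.DataFrame:
        """Long-format table matching the ``quantification`` schema."""
        rows = []
        for s in self.ip_norm.columns:
            frame = pd.DataFrame({
                "probe_id": self.ip_norm.index,
                "sample_id": s,
                "ip_norm": self.ip_norm[s].values,
                "sup_norm": self.sup_norm[s].values,
                "m6a_quantity": self.ip_norm[s].values,
                "percent_modified": self.percent_modified[s].values,
                "out_of_range": self.out_of_range[s].values,
                "retained": self.retained.reindex(self.ip_norm.index).values,
            })
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def normalize_channel(
    matrix: ChannelMatrix,
    spike_ids: Iterable[str],
    floor_epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-array log2 spike-in normalization of one channel.

    ``floor_epsilon``, when set, clamps non-positive raw intensities instead
    of raising (they are reported in the log); by default they are an error
    because a non-positive fluorescence value indicates a corrupt export.
    """
    spike_ids = list(spike_ids)
    if not spike_ids:
        raise QuantificationError("empty spike-in set")
    missing = [p for p in spike_ids if p not in matrix.values.index]
    if missing:
        raise QuantificationError(f"spike-in probes absent from matrix: {missing}")

    raw = matrix.values.astype(float)
    if (raw.values <= 0).any():
        if floor_epsilon is None:
            bad = int((raw.values <= 0).sum())
            raise QuantificationError(
                f"{bad} raw intensities <= 0 in channel {matrix.channel}; "
                "set floor_epsilon to clamp"
            )
        raw = raw.clip(lower=floor_epsilon)

    log2raw = np.log2(raw)
    # arithmetic mean of log2 spike-in values = log2 geometric mean, per array
    spike_mean = log2raw.loc[spike_ids].mean(axis=0)
    return log2raw.sub(spike_mean, axis=1)


def percent_modified(
    ip_norm: pd.DataFrame | np.ndarray | float,
    sup_norm: pd.DataFrame | np.ndarray | float,
    scale: str = "log2_normalized",
) -> tuple:
    """Modification stoichiometry IP/(IP+Sup) with out-of-range flagging.

    Returns ``(fraction, out_of_range)``; a zero denominator yields NaN
    (serialized as NA) with the flag set.
    """
    if scale not in PERCENT_MODIFIED_SCALES:
        raise QuantificationError(f"unknown percent_modified scale {scale!r}")
    ip = np.asarray(ip_norm, dtype=float)
    sup = np.asarray(sup_norm, dtype=float)
    if scale == "linear":
        ip, sup = np.exp2(ip), np.exp2(sup)
    denom = ip + sup
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom == 0, np.nan, ip / denom)
    out = np.isnan(frac) | (frac < 0) | (frac > 1)
    frac = np.clip(frac, 0.0, 1.0)
    if isinstance(ip_norm, pd.DataFrame):
        frac = pd.DataFrame(frac, index=ip_norm.index, columns=ip_norm.columns)
        out = pd.DataFrame(out, index=ip_norm.index, columns=ip_norm.columns)
        return frac, out
    if np.ndim(frac) == 0:
        return float(frac), bool(out)
    return frac, out


def retain_probes(qc_flags: pd.DataFrame, min_pm: int = 4) -> pd.Series:
    """Retain probes with a P or M flag in at least ``min_pm`` samples."""
    if min_pm < 1:
        raise QuantificationError("min_pm must be >= 1")
    pm_count = qc_flags.isin(["P", "M"]).sum(axis=1)
    return pm_count >= min_pm


def quantify(
    ip: ChannelMatrix,
    sup: ChannelMatrix,
    spike_ids: Iterable[str],
    min_pm: int = 4,
    scale: str = "log2_normalized",
    floor_epsilon: float | None = None,
) -> QuantificationResult:
    """Full quantification stage: normalize both channels, derive %Modified,
    apply the QC retention rule, and drop spike-in probes from the result.

    Retention uses the IP-channel flags (the channel the m6A quantity is
    read from); it is applied after normalization and before any contrast.
    """
    spike_ids = list(spike_ids)
    ip_norm = normalize_channel(ip, spike_ids, floor_epsilon=floor_epsilon)
    sup_norm = normalize_channel(sup, spike_ids, floor_epsilon=floor_epsilon)
    if list(ip_norm.index) != list(sup_norm.index):
        raise QuantificationError("IP and Sup matrices disagree on probes")
    if list(ip_norm.columns) != list(sup_norm.columns):
        raise QuantificationError("IP and Sup matrices disagree on samples")

    keep = [p for p in ip_norm.index if p not in set(spike_ids)]
    ip_norm, sup_norm = ip_norm.loc[keep], sup_norm.loc[keep]
    frac, out = percent_modified(ip_norm, sup_norm, scale=scale)
    retained = retain_probes(ip.qc_flags.loc[keep], min_pm=min_pm)
    return QuantificationResult(
        ip_norm=ip_norm,
        sup_norm=sup_norm,
        percent_modified=frac,
        out_of_range=out,
        retained=retained,
        scale=scale,
    )
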