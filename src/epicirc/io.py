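"""Readers, writers and the in-memory data model for two-channel array tables.

A raw channel table is tab- or comma-delimited (dialect picked by file
extension: ``.csv`` means comma, anything else tab) with one probe per row.
The first column is ``probe_id``; every sample contributes an intensity
column named ``<sample>`` optionally paired with a QC flag column named
``<sample>_flag`` holding one of ``P`` (present), ``M`` (marginal) or ``A``
(absent).  Missing flag columns are treated as all-P with a logged warning;
an unparseable flag token is stored as ``A`` and logged.  ``NA`` is the sole
missing-value token in every table this module writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("IP_Cy5", "Sup_Cy3")
QC_FLAGS = ("P", "M", "A")
CATEGORIES = ("exonic", "intronic", "sense_overlapping", "antisense", "intergenic")
STRANDS = ("+", "-", "unknown")

#: Deterministic column order for each result-table schema.
SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "quantification": (
        "probe_id", "sample_id", "ip_norm", "sup_norm", "m6a_quantity",
        "percent_modified", "out_of_range", "retained",
    ),
    "contrast": (
        "probe_id", "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
        "log2fc", "fc", "p", "q", "call", "zero_variance",
    ),
    "diagnostics": (
        "contrast", "observed_sig_count", "permutation_iterations",
        "empirical_p", "ks_D", "ks_p", "cohens_d", "mde_log2fc", "power",
        "alpha", "sd_pooled", "seed",
    ),
    "roc": ("probe_id", "auc", "direction", "n_pos", "n_neg"),
    "sets": ("region", "direction", "count"),
    "enrichment": ("term_id", "term_name", "k", "K", "n", "N", "p", "q", "significant"),
    "survival": (
        "marker", "n_high", "n_low", "logrank_chi2", "logrank_p", "hr",
        "ci_low", "ci_high", "cox_p",
    ),
}


class ArrayIOError(ValueError):
    """Malformed input table (duplicate ids, bad numbers, unknown enum values)."""


@dataclass
class ChannelMatrix:
    """Raw probe x sample intensities for one channel plus per-cell QC flags."""

    channel: str
    values: pd.DataFrame        # float intensities, index=probe_id, columns=sample_id
    qc_flags: pd.DataFrame      # str flags in {P, M, A}, same shape

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ArrayIOError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.values.shape != self.qc_flags.shape:
            raise ArrayIOError("values and qc_flags must have identical shape")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ArrayIOError(f"duplicate probe ids: {dups}")
        if self.values.columns.duplicated().any():
            raise ArrayIOError("duplicate sample ids")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    probe_id: str
    host_gene: str
    chromosome: str
    strand: str
    category: str | None
    is_spike_in: bool = False
    start: int | None = None   # 0-based, half-open; optional, for BED export
    end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ArrayIOError(f"{self.probe_id}: unknown strand {self.strand!r}")
        # spike-in probes carry no genomic category requirement
        if not self.is_spike_in and self.category not in CATEGORIES:
            raise ArrayIOError(
                f"{self.probe_id}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_channel_matrix(path: str | Path, channel: str) -> ChannelMatrix:
    """Read a raw intensity table for one channel.

    Raises on duplicate probe ids and non-numeric intensities; an unknown
    flag token becomes ``A`` with a warning, a missing flag column becomes
    all-``P`` with a warning.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.columns[0] != "probe_id":
        raise ArrayIOError(f"{path}: first column must be 'probe_id', got {raw.columns[0]!r}")
    probe_ids = raw["probe_id"]
    if probe_ids.duplicated().any():
        dups = probe_ids[probe_ids.duplicated()].unique().tolist()
        raise ArrayIOError(f"{path}: duplicate probe ids {dups}")

    sample_cols = [c for c in raw.columns[1:] if not c.endswith("_flag")]
    values = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    flags = pd.DataFrame(index=values.index)
    for s in sample_cols:
        try:
            values[s] = pd.to_numeric(raw[s].values, errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[s], errors="coerce").isna()][0]
            raise ArrayIOError(
                f"{path}: non-numeric intensity in column {s!r}, row "
                f"{probe_ids.iloc[bad]!r}"
            ) from None
        flag_col = f"{s}_flag"
        if flag_col in raw.columns:
            f = raw[flag_col].str.strip().str.upper().values
            bad_mask = ~np.isin(f, QC_FLAGS)
            if bad_mask.any():
                bad_tokens = sorted(set(f[bad_mask]))
                logger.warning(
                    "%s: %d unparseable flag token(s) %s in column %s set to A",
                    path, int(bad_mask.sum()), bad_tokens, flag_col,
                )
                f = np.where(bad_mask, "A", f)
            flags[s] = f
        else:
            logger.warning("%s: no flag column for sample %r; assuming all P", path, s)
            flags[s] = "P"
    return ChannelMatrix(channel=channel, values=values, qc_flags=flags)


def write_channel_matrix(matrix: ChannelMatrix, path: str | Path) -> None:
    """Write a channel matrix in the dialect :func:`read_channel_matrix` reads."""
    out = pd.DataFrame({"probe_id": matrix.probe_ids})
    for s in matrix.sample_ids:
        out[s] = [_fmt(v) for v in matrix.values[s].values]
        out[f"{s}_flag"] = matrix.qc_flags[s].values
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read a probe annotation table; validates categories, strands, uniqueness."""
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"probe_id", "host_gene", "chromosome", "strand", "category", "is_spike_in"}
    missing = required - set(raw.columns)
    if missing:
        raise ArrayIOError(f"{path}: missing annotation columns {sorted(missing)}")
    if raw["probe_id"].duplicated().any():
        dups = raw["probe_id"][raw["probe_id"].duplicated()].unique().tolist()
        raise ArrayIOError(f"{path}: duplicate probe ids {dups}")
    records = []
    for row in raw.itertuples(index=False):
        token = str(row.is_spike_in).strip().lower()
        if token in _TRUE:
            spike = True
        elif token in _FALSE:
            spike = False
        else:
            raise ArrayIOError(f"{path}: bad is_spike_in value {row.is_spike_in!r}")
        category = row.category.strip() or None
        records.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                host_gene=row.host_gene,
                chromosome=row.chromosome,
                strand=row.strand.strip(),
                category=category,
                is_spike_in=spike,
                start=int(row.start) if "start" in raw.columns and row.start != "" else None,
                end=int(row.end) if "end" in raw.columns and row.end != "" else None,
            )
        )
    return records


def write_annotation(records: Sequence[ProbeAnnotation], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "probe_id": r.probe_id, "host_gene": r.host_gene,
            "chromosome": r.chromosome, "strand": r.strand,
            "category": r.category if r.category is not None else "",
            "is_spike_in": str(r.is_spike_in).lower(),
            "start": "" if r.start is None else r.start,
            "end": "" if r.end is None else r.end,
        })
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def annotation_frame(records: Sequence[ProbeAnnotation]) -> pd.DataFrame:
    """Annotation records as a DataFrame indexed by probe_id."""
    return pd.DataFrame(
        {
            "host_gene": [r.host_gene for r in records],
            "chromosome": [r.chromosome for r in records],
            "strand": [r.strand for r in records],
            "category": [r.category for r in records],
            "is_spike_in": [r.is_spike_in for r in records],
        },
        index=pd.Index([r.probe_id for r in records], name="probe_id"),
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: columns sample_id, group. Sample ids must be unique."""
    sheet = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise ArrayIOError(f"{path}: sample sheet needs columns sample_id, group")
    if sheet["sample_id"].duplicated().any():
        raise ArrayIOError(f"{path}: duplicate sample ids")
    return sheet[["sample_id", "group"]]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[["sample_id", "group"]].to_csv(path, sep=_sep_for(path), index=False)


def validate_study(
    ip: ChannelMatrix,
    sup: ChannelMatrix,
    annotation: Sequence[ProbeAnnotation],
    samples: pd.DataFrame,
) -> dict:
    """Cross-check the four study inputs; returns a structured report.

    Raises :class:`ArrayIOError` on inconsistencies a downstream stage could
    not recover from (mismatched probes/samples, unannotated probes,
    samples missing from the sheet).
    """
    if ip.probe_ids != sup.probe_ids:
        raise ArrayIOError("IP and Sup matrices disagree on probe ids/order")
    if ip.sample_ids != sup.sample_ids:
        raise ArrayIOError("IP and Sup matrices disagree on sample ids/order")
    ann_ids = {a.probe_id for a in annotation}
    unannotated = [p for p in ip.probe_ids if p not in ann_ids]
    if unannotated:
        raise ArrayIOError(f"probes without annotation: {unannotated[:5]}...")
    sheet_ids = set(samples["sample_id"])
    missing = [s for s in ip.sample_ids if s not in sheet_ids]
    if missing:
        raise ArrayIOError(f"samples missing from sample sheet: {missing}")
    groups = samples.set_index("sample_id").loc[ip.sample_ids, "group"]
    spikes = sorted(a.probe_id for a in annotation if a.is_spike_in)
    return {
        "n_probes": len(ip.probe_ids),
        "n_spike_in": len(spikes),
        "n_samples": len(ip.sample_ids),
        "groups": groups.value_counts().to_dict(),
        "nonpositive_ip": int((ip.values.values <= 0).sum()),
        "nonpositive_sup": int((sup.values.values <= 0).sum()),
    }


def _fmt(value) -> str:
    """Serialize one cell: floats to 6 significant digits, NaN as NA."""
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value)).lower()
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_result_table(records: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a result table with deterministic column order and NA tokens."""
    if schema_name not in SCHEMAS:
        raise ArrayIOError(
            f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}"
        )
    cols = SCHEMAS[schema_name]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ArrayIOError(f"schema {schema_name!r}: missing columns {missing}")
    out = records[list(cols)].copy()
    for c in cols:
        out[c] = [_fmt(v) for v in out[c].values]
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_result_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_result_table`."""
    if schema_name not in SCHEMAS:
        raise ArrayIOError(f"unknown schema {schema_name!r}")
    frame = pd.read_csv(
        path, sep=_sep_for(path), na_values=["NA"], keep_default_na=False
    )
    return frame


def export_bed(
    annotation: Sequence[ProbeAnnotation],
    path: str | Path,
    log2fc: Mapping[str, float] | None = None,
) -> None:
    """BED6 export of probe loci (0-based half-open); score = round(log2fc*100)."""
    rows = []
    for a in annotation:
        if a.start is None or a.end is None or a.is_spike_in:
            continue
        score = 0
        if log2fc is not None and a.probe_id in log2fc:
            score = int(round(100 * log2fc[a.probe_id]))
        strand = a.strand if a.strand in ("+", "-") else "."
        rows.append((a.chromosome, a.start, a.end, a.probe_id, score, strand))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
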