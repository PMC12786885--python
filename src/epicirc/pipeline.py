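"""End-to-end orchestration of the analysis over one (synthetic) study.

Runs simulate -> quantify -> differential contrasts (TNBC vs each luminal
group and vs their pool) -> diagnostics -> ROC on the top-ranked probes ->
cross-contrast set logic and category tallies -> host-gene enrichment
against generator-defined gene sets -> median-split survival on a
simulated cohort.  Used by the numbered analysis drivers, the acceptance
script and the end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential, diagnostics, roc, sets, survival
from .io import annotation_frame
from .quantify import QuantificationResult, quantify
from .simulate import SimulatedStudy, simulate_array, simulate_survival


@dataclass
class StudyResults:
    study: SimulatedStudy
    quant: QuantificationResult
    contrasts: dict[str, pd.DataFrame]
    memberships: pd.DataFrame
    diagnostics: dict[str, diagnostics.DiagnosticsReport]
    roc_table: pd.DataFrame
    venn: dict[str, dict[frozenset, int]]
    consistent: dict[str, list[str]]
    categories: pd.DataFrame
    enrichment: pd.DataFrame
    survival_fit: survival.SurvivalFit


def default_contrast_plan(samples: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(name, group_a, group_b) with group_a the first (case) group against
    every other group; a pooled 'rest' contrast is added when >= 3 groups."""
    groups = list(dict.fromkeys(samples["group"]))
    case = groups[0]
    plan = [(f"{case}_vs_{g}", case, g) for g in groups[1:]]
    return plan


def run_study(
    seed: int = 0,
    n_probes: int = 2000,
    frac_dm: float = 0.05,
    B_permutations: int = 200,
    top_k: int = 20,
    survival_n: int = 300,
    survival_hr: float = 2.4,
    **simulate_kwargs,
) -> StudyResults:
    """Simulate a study and run every analysis stage on it."""
    rng = np.random.default_rng(seed)
    sim_seed, perm_seed, surv_seed = rng.integers(0, 2**31 - 1, size=3)
    study = simulate_array(
        n_probes=n_probes, frac_dm=frac_dm, seed=int(sim_seed), **simulate_kwargs
    )
    quant = quantify(study.ip, study.sup, study.spike_ids)

    plan = default_contrast_plan(study.samples)
    # pooled contrast: case group vs all other groups together
    groups = list(dict.fromkeys(study.samples["group"]))
    case = groups[0]
    pooled_sheet = study.samples.copy()
    pooled_sheet["group"] = np.where(pooled_sheet["group"] == case, case, "Rest")

    contrasts: dict[str, pd.DataFrame] = {}
    reports: dict[str, diagnostics.DiagnosticsReport] = {}
    for name, ga, gb in plan:
        contrasts[name] = differential.contrast(quant, study.samples, ga, gb)
    contrasts[f"{case}_vs_Rest"] = differential.contrast(quant, pooled_sheet, case, "Rest")

    first = plan[0]
    report, _ = diagnostics.diagnose(
        quant, study.samples, first[1], first[2],
        contrasts[first[0]]["p"].values,
        B=B_permutations, seed=int(perm_seed),
    )
    reports[first[0]] = report

    memberships = sets.membership_table(contrasts)

    hyper, hypo = differential.top_k(contrasts[f"{case}_vs_Rest"], k=top_k)
    probes = list(hyper["probe_id"]) + list(hypo["probe_id"])
    if probes:
        roc_table, _ = roc.rank_biomarkers(
            quant, pooled_sheet, case, "Rest", probes
        )
    else:
        roc_table = pd.DataFrame(columns=["probe_id", "auc", "direction", "n_pos", "n_neg"])

    contrast_names = list(contrasts)
    venn = {
        d: sets.venn_counts(memberships, contrast_names[:3], d)
        for d in ("hyper", "hypo")
    }
    consistent = {
        d: sets.consistent_specific_set(memberships, contrast_names, d)
        for d in ("hyper", "hypo")
    }
    ann = annotation_frame(study.annotation)
    categories = sets.category_distribution(memberships, ann)

    # enrichment: gene sets built from the annotation (one set per
    # chromosome) against the retained-probe host-gene universe
    retained_probes = quant.retained[quant.retained].index
    universe = sets.host_gene_query(retained_probes, ann)
    gene_sets = {}
    for chrom, sub in ann[~ann["is_spike_in"]].groupby("chromosome"):
        gene_sets[f"chrom:{chrom}"] = (f"host genes on {chrom}", set(sub["host_gene"]))
    sig_probes = memberships.index[(memberships != "ns").any(axis=1) & (memberships != "untested").all(axis=1)]
    sig_probes = [p for p in sig_probes if memberships.loc[p].isin(["hyper", "hypo"]).any()]
    query = sets.host_gene_query(sig_probes, ann) if sig_probes else []
    enrichment = sets.hypergeometric_ora(query, gene_sets, universe)

    cohort = simulate_survival(n=survival_n, true_hr=survival_hr, seed=int(surv_seed))
    fit = survival.survival_fit(cohort, marker="synthetic_marker")

    return StudyResults(
        study=study, quant=quant, contrasts=contrasts, memberships=memberships,
        diagnostics=reports, roc_table=roc_table, venn=venn,
        consistent=consistent, categories=categories, enrichment=enrichment,
        survival_fit=fit,
    )
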