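"""Structured-text statistics report for a lineage tree."""

from __future__ import annotations

import numpy as np

from . import analytics
from .lineage import LineageTree

__all__ = ["build_report", "write_report"]


def build_report(tree: LineageTree) -> str:
    lines = ["# bcelldyn lineage statistics report", ""]

    stats = analytics.fate_fractions(tree)
    raw = analytics.raw_division_fractions(tree)
    lines.append("[per-generation fate fractions]")
    lines.append("generation\tn_cells\tn_eligible\tfrac_divided_window\t"
                 "frac_died_window\terr_1_over_n\tfrac_divided_raw")
    for row in stats.table.itertuples(index=False):
        lines.append(
            f"{row.generation}\t{row.n_cells}\t{row.n_eligible}\t"
            f"{row.fraction_divided:.4f}\t{row.fraction_died:.4f}\t"
            f"{row.err:.4f}\t{raw.get(row.generation, float('nan')):.4f}"
        )
    for note in stats.notes:
        lines.append(f"# note: {note}")
    lines.append("")

    try:
        kin = analytics.kin_correlations(tree)
        lines.append("[kin correlations]")
        lines.append("relation\tsame_fate_prob\tpr_dtgro_le_4h\t"
                     "r2_interdivision\tr2_lifespan\tn_pairs")
        for rel in ("sister", "cousin"):
            s = kin[rel]
            fmt = lambda x: "NA" if x is None else f"{x:.4f}"
            lines.append(f"{rel}\t{fmt(s['same_fate_prob'])}\t"
                         f"{fmt(s['pr_dtgro_le_4h'])}\t{fmt(s['r2_interdivision'])}\t"
                         f"{fmt(s['r2_lifespan'])}\t{s['n_pairs']}")
    except ValueError as exc:
        lines.append(f"[kin correlations] unavailable: {exc}")
    lines.append("")

    # race-vs-decision lower bound from generation-0 samples
    gen0 = stats.timings.get(0, {})
    tdie0 = np.asarray(gen0.get("tdie", []), float)
    classes, _ = analytics.classify_all(tree)
    tgro0 = []
    for rec in tree.records():
        if rec.generation == 0 and classes.get(rec.cell_id) == "grower" \
                and rec.volumes is not None and len(rec.volumes) >= 5:
            tgro0.append(analytics.fit_growth(rec).t_gro)
    founders = tree.founders()
    f_resp = float((founders["fate"] == "divided").mean()) if len(founders) else 0.0
    lines.append("[race-vs-decision lower bound, generation 0]")
    if len(tgro0) and len(tdie0):
        rb = analytics.race_lower_bound(tgro0, tdie0, f_resp)
        # observed fraction of dying generation-0 cells classified as growers
        died0 = [r for r in tree.records()
                 if r.generation == 0 and r.fate == "died"]
        grew_and_died = [r for r in died0 if classes.get(r.cell_id) == "grower"]
        observed = len(grew_and_died) / len(died0) if died0 else float("nan")
        lines.append(f"f_resp (gen-0 dividing fraction)\t{f_resp:.4f}")
        lines.append(f"race_lower_bound\t{rb.p_race:.4f}")
        lines.append(f"decision_expectation\t{rb.p_decision:.4f}")
        lines.append(f"observed_P(grew|died)\t{observed:.4f}")
    else:
        lines.append("unavailable: needs generation-0 growth-onset and death samples")
    lines.append("")

    pop = analytics.population_summaries(tree)
    lines.append("[population summaries]")
    lines.append(f"max_relative_count\t{pop.max_relative_count:.4f}")
    lines.append(f"expected_divisions_per_progenitor\t{pop.expected_divisions:.4f}")
    idt = pop.mean_interdivision_gen1plus
    lines.append("mean_interdivision_gen1plus_h\t"
                 + ("NA" if idt is None else f"{idt:.4f}"))
    lines.append(f"end_relative_count\t{pop.end_relative_count:.4f}")
    lines.append("")
    return "\n".join(lines)


def write_report(tree: LineageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(build_report(tree))
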