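"""Report assembly and rendering (text / CSV / JSON).

A :class:`ReportBundle` collects, for a cohort and a set of
replicate-combination rules: sensitivity/specificity with counts and
Wilson CIs, detection rates per diagnostic group, the pairwise chi-square
comparison matrices, the number of subjects excluded for failed internal
controls, and a provenance block (input, assay, seed when simulated,
package version). Counts always accompany percentages so downstream
chi-square checks never have to re-parse a rounded percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from . import __version__
from .calling import AlgorithmSpec, BinaryCall, call_subject
from .cohort_io import AssayConfig, Cohort, Group
from .performance import (ContingencyTable2x2, ProportionEstimate,
                          algorithm_performance,
                          averaged_single_replicate_performance,
                          pdr_by_stratum, pearson_chi2)


def _prop_dict(est: ProportionEstimate) -> dict:
    return {"positives": est.positives, "total": est.total,
            "percent": round(100 * est.proportion, 1),
            "ci_low": round(est.ci_low, 4),
            "ci_high": round(est.ci_high, 4)}


@dataclass
class ReportBundle:
    performance: dict
    pdr_by_group: dict
    chi2_matrix: dict
    exclusions: int
    provenance: dict

    def to_dict(self) -> dict:
        return {"performance": self.performance,
                "pdr_by_group": self.pdr_by_group,
                "chi2_matrix": self.chi2_matrix,
                "exclusions": self.exclusions,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = []
        lines.append("Performance by algorithm")
        lines.append(f"{'algorithm':<12}{'sensitivity':<24}"
                     f"{'specificity':<24}")
        for alg, cells in self.performance.items():
            def fmt(c):
                if "positives" in c:
                    return (f"{c['percent']:.1f}% "
                            f"({c['positives']}/{c['total']})")
                return f"{c['percent']:.1f}% (averaged)"
            lines.append(f"{alg:<12}{fmt(cells['sensitivity']):<24}"
                         f"{fmt(cells['specificity']):<24}")
        lines.append("")
        lines.append("Positive detection rate by group")
        algs = [a for a in self.pdr_by_group]
        groups = list(next(iter(self.pdr_by_group.values())))
        header = f"{'group':<12}" + "".join(f"{a:<20}" for a in algs)
        lines.append(header)
        for g in groups:
            row = f"{g:<12}"
            for a in algs:
                c = self.pdr_by_group[a][g]
                row += (f"{c['percent']:.1f}% "
                        f"({c['positives']}/{c['total']})").ljust(20)
            lines.append(row)
        lines.append("")
        lines.append("Pairwise chi-square (statistic, p)")
        for metric, pairs in self.chi2_matrix.items():
            for pair, res in pairs.items():
                lines.append(f"  {metric} {pair}: chi2 = "
                             f"{res['statistic']:.2f}, p = "
                             f"{res['p_value']:.4f}")
        lines.append("")
        lines.append(f"Subjects excluded (failed control): "
                     f"{self.exclusions}")
        lines.append("Provenance: " + json.dumps(self.provenance,
                                                 sort_keys=True))
        return "\n".join(lines) + "\n"

    def to_csv_files(self, directory: str | Path) -> list[Path]:
        """One CSV per table; returns the written paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        perf = directory / "performance.csv"
        with open(perf, "w", encoding="utf-8") as fh:
            fh.write("algorithm,metric,percent,positives,total,"
                     "ci_low,ci_high\n")
            for alg, cells in self.performance.items():
                for metric in ("sensitivity", "specificity"):
                    c = cells[metric]
                    fh.write(
                        f"{alg},{metric},{c['percent']},"
                        f"{c.get('positives', '')},{c.get('total', '')},"
                        f"{c.get('ci_low', '')},{c.get('ci_high', '')}\n")
        written.append(perf)
        pdr = directory / "pdr_by_group.csv"
        with open(pdr, "w", encoding="utf-8") as fh:
            fh.write("algorithm,group,percent,positives,total\n")
            for alg, groups in self.pdr_by_group.items():
                for g, c in groups.items():
                    fh.write(f"{alg},{g},{c['percent']},"
                             f"{c['positives']},{c['total']}\n")
        written.append(pdr)
        chi = directory / "chi2_matrix.csv"
        with open(chi, "w", encoding="utf-8") as fh:
            fh.write("metric,comparison,statistic,p_value\n")
            for metric, pairs in self.chi2_matrix.items():
                for pair, res in pairs.items():
                    fh.write(f"{metric},{pair},{res['statistic']:.4f},"
                             f"{res['p_value']:.6g}\n")
        written.append(chi)
        return written


def build_report(cohort: Cohort, assay: AssayConfig,
                 algorithms: Iterable[str] = ("1/3", "2/3", "1/1", "3/3"),
                 case_groups=(Group.CRC,),
                 control_groups=(Group.NED,)) -> ReportBundle:
    """Assemble the full evaluation report for a cohort."""
    algorithms = list(algorithms)
    performance: dict = {}
    pdr: dict = {}
    sens_counts: dict = {}
    spec_counts: dict = {}
    exclusions = 0
    for name in algorithms:
        alg = AlgorithmSpec.from_name(name)
        if alg.is_averaged:
            sens, spec = averaged_single_replicate_performance(
                cohort, assay, case_groups, control_groups)
            performance[name] = {
                "sensitivity": {"percent": round(100 * sens, 1)},
                "specificity": {"percent": round(100 * spec, 1)}}
            continue
        sens_est, spec_est = algorithm_performance(
            cohort, assay, alg, case_groups, control_groups)
        performance[name] = {"sensitivity": _prop_dict(sens_est),
                             "specificity": _prop_dict(spec_est)}
        sens_counts[name] = sens_est
        spec_counts[name] = spec_est
        table = pdr_by_stratum(cohort, assay, alg, "group")
        pdr[name] = {
            str(label): {"positives": int(row.positives),
                         "total": int(row.total),
                         "percent": round(100 * row.proportion, 1)}
            for label, row in table.iterrows()}
        exclusions = sum(
            call_subject(s, assay, alg) is BinaryCall.INVALID
            for s in cohort.subjects)

    chi2_matrix: dict = {"sensitivity": {}, "specificity": {}}
    named = list(sens_counts)
    for i, a in enumerate(named):
        for b in named[i + 1:]:
            for metric, counts in (("sensitivity", sens_counts),
                                   ("specificity", spec_counts)):
                t = ContingencyTable2x2.from_proportions(
                    counts[a].positives, counts[a].total,
                    counts[b].positives, counts[b].total)
                res = pearson_chi2(t)
                chi2_matrix[metric][f"{a} vs {b}"] = {
                    "statistic": round(res.statistic, 4),
                    "p_value": res.p_value}

    provenance = {
        "input": cohort.provenance,
        "assay": {"name": assay.name,
                  "n_replicates": assay.n_replicates,
                  "k_required": assay.k_required,
                  "ct_cutoff": assay.ct_cutoff,
                  "max_cycles": assay.max_cycles,
                  "plasma_equivalent_ml": assay.plasma_equivalent_ml},
        "algorithms": algorithms,
        "version": __version__,
    }
    # surface the seed for simulated inputs
    if "seed=" in (cohort.provenance or ""):
        seed_part = cohort.provenance.split("seed=")[1]
        provenance["seed"] = int("".join(
            ch for ch in seed_part.split(",")[0] if ch.isdigit()))
    return ReportBundle(performance=performance, pdr_by_group=pdr,
                        chi2_matrix=chi2_matrix, exclusions=exclusions,
                        provenance=provenance)
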