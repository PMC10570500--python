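"""End-to-end longitudinal rich-club analysis.

`LongitudinalRichClubAnalysis` is the model object: it binds a two-session,
two-group cohort of ROI time series to a region table and an
`AnalysisConfig`, and `fit()` runs the full chain - per-scan FC construction
and FWE thresholding, global/nodal graph metrics with rewired-null
small-worldness, rich/feeder/local connectivity sums, per-group two-tailed
Wilcoxon signed-rank tests (FDR across nodes for nodal metrics), Spearman
correlations between treatment-group rich-club connectivity change and
symptom-score change (post minus pre), and a paired sign-flip NBS per group.
The returned `RichClubResults` carries every intermediate table, exposes
`summary()` and writes a deterministic JSON/TSV report.

Group analyses are independent (no group-by-time interaction), matching the
separate pre/post contrasts the design calls for.  Everything is
deterministic for a fixed `config.seed`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RegionTable, load_region_table, partition_nodes
from .fc import pearson_fc, threshold_fwe
from .metrics import global_metrics, nodal_metrics
from .nbs import nbs_paired
from .richclub import richclub_summary
from .stats import StatResult, bh_fdr, wilcoxon_signed_rank, spearman
from .synthetic import CONTROL, TREATMENT, Cohort, load_cohort

__all__ = ["AnalysisConfig", "LongitudinalRichClubAnalysis", "RichClubResults",
           "run_longitudinal_analysis"]

log = logging.getLogger("richnet.pipeline")

NODAL_METRIC_NAMES = ("degree", "strength", "efficiency", "betweenness")
GLOBAL_TEST_NAMES = ("overall_strength", "global_efficiency", "sigma",
                     "rich_connectivity", "feeder_connectivity", "local_connectivity")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of one analysis run."""

    fwe_alpha: float = 0.05
    fwe_method: str = "bonferroni"
    metric_mode: str = "weighted"
    n_null: int = 100
    n_swaps_per_edge: int = 10
    nbs_threshold: float = 3.0
    nbs_permutations: int = 5000
    nbs_direction: str = "positive"
    nbs_on_raw: bool = True
    fdr_q: float = 0.05
    seed: int = 0
    manifest: str = None
    region_table: str = None
    output_dir: str = None

    def __post_init__(self):
        if not 0 < self.fwe_alpha < 1 or not 0 < self.fdr_q < 1:
            raise ValueError("alpha/q levels must lie in (0, 1)")
        if self.nbs_threshold <= 0:
            raise ValueError("nbs_threshold must be positive")
        if self.n_null < 1 or self.nbs_permutations < 1:
            raise ValueError("n_null and nbs_permutations must be positive")


def _safe_wilcoxon(pre_vals, post_vals) -> StatResult:
    """Wilcoxon over finite pairs; too few informative pairs -> p = NaN."""
    pre_vals = np.asarray(pre_vals, float)
    post_vals = np.asarray(post_vals, float)
    ok = np.isfinite(pre_vals) & np.isfinite(post_vals)
    try:
        return wilcoxon_signed_rank(pre_vals[ok], post_vals[ok])
    except ValueError:
        return StatResult(statistic=float("nan"), p_value=float("nan"),
                          n_effective=int(ok.sum()), method="insufficient")


@dataclass
class GroupResults:
    """Everything computed for one group."""

    label: str
    subjects: list
    global_table: pd.DataFrame          # subject x session global metrics
    richclub_table: pd.DataFrame        # subject x session class sums
    nodal: dict                         # metric -> {"pre": (s, n), "post": (s, n)}
    global_tests: dict                  # name -> StatResult
    nodal_tests: dict                   # metric -> {"p","p_fdr","reject"}
    nbs: object


@dataclass
class RichClubResults:
    """Fitted results; statsmodels-style container with summary()."""

    config: AnalysisConfig
    region_table: RegionTable
    groups: dict                        # label -> GroupResults
    spearman: dict                      # scale -> StatResult (treatment group)
    skipped: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Longitudinal rich-club connectome analysis", "=" * 44]
        for label, g in self.groups.items():
            lines.append(f"\nGroup: {label}  (n = {len(g.subjects)})")
            lines.append("  Wilcoxon signed-rank, post vs pre (two-tailed):")
            for name in GLOBAL_TEST_NAMES:
                res = g.global_tests[name]
                lines.append(
                    f"    {name:<20s} W = {res.statistic:8.2f}   p = {res.p_value:.4f}"
                    f"   (n = {res.n_effective}, {res.method})"
                )
            for metric, t in g.nodal_tests.items():
                k = int(t["reject"].sum())
                lines.append(f"  Nodal {metric}: {k} region(s) significant at FDR q < "
                             f"{self.config.fdr_q:g}")
            if g.nbs.components:
                c0 = g.nbs.components[0]
                lines.append(f"  NBS: largest component {c0.size} edges, p = {c0.p_value:.4f}"
                             f"  ({g.nbs.n_permutations} permutations, t > "
                             f"{g.nbs.threshold:g} {g.nbs.direction})")
            else:
                lines.append("  NBS: no suprathreshold components")
        if self.spearman:
            lines.append("\nSpearman: rich-club connectivity change vs score change "
                         "(treatment group)")
            for scale, res in self.spearman.items():
                lines.append(f"    {scale:<8s} rho = {res.statistic: .3f}   "
                             f"p = {res.p_value:.4f}   (n = {res.n_effective})")
        for label, why in self.skipped.items():
            lines.append(f"\nGroup {label} skipped: {why}")
        return "\n".join(lines)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def num(v):
            v = float(v)
            return None if not np.isfinite(v) else v

        def stat(res: StatResult) -> dict:
            return {"statistic": num(res.statistic), "p_value": num(res.p_value),
                    "n_effective": int(res.n_effective), "method": res.method}

        out = {
            "provenance": {
                "package": "richnet",
                "version": __version__,
                "config": {k: (str(v) if isinstance(v, Path) else v)
                           for k, v in asdict(self.config).items()},
            },
            "groups": {},
            "spearman": {k: stat(v) for k, v in self.spearman.items()},
            "skipped": dict(self.skipped),
        }
        names = self.region_table.names
        for label, g in self.groups.items():
            comp_list = []
            for c in g.nbs.components:
                comp_list.append({
                    "size": int(c.size),
                    "p_value": num(c.p_value),
                    "edges": [[names[i], names[j]] for i, j in c.edges.tolist()],
                })
            out["groups"][label] = {
                "n_subjects": len(g.subjects),
                "global_tests": {k: stat(v) for k, v in g.global_tests.items()},
                "nodal_significant": {
                    m: [names[i] for i in np.flatnonzero(t["reject"])]
                    for m, t in g.nodal_tests.items()
                },
                "nbs": {
                    "threshold": g.nbs.threshold,
                    "direction": g.nbs.direction,
                    "n_permutations": g.nbs.n_permutations,
                    "components": comp_list,
                },
            }
        return out

    def save(self, outdir) -> Path:
        """Write report.json plus TSV tables; returns the report path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report = outdir / "report.json"
        report.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n")
        gl = pd.concat([g.global_table for g in self.groups.values()], ignore_index=True)
        gl.to_csv(outdir / "global_metrics.tsv", sep="\t", index=False,
                  float_format="%.10g")
        rc = pd.concat([g.richclub_table for g in self.groups.values()], ignore_index=True)
        rc.to_csv(outdir / "richclub.tsv", sep="\t", index=False, float_format="%.10g")
        nodal_rows = []
        names = self.region_table.names
        for label, g in self.groups.items():
            for metric, t in g.nodal_tests.items():
                for i, name in enumerate(names):
                    nodal_rows.append({
                        "group": label, "metric": metric, "region": name,
                        "p": t["p"][i], "p_fdr": t["p_fdr"][i],
                        "significant": int(t["reject"][i]),
                    })
        pd.DataFrame(nodal_rows).to_csv(outdir / "nodal_metrics.tsv", sep="\t",
                                        index=False, float_format="%.10g")
        nbs_doc = {label: self.to_dict()["groups"][label]["nbs"]
                   for label in self.groups}
        (outdir / "nbs.json").write_text(json.dumps(nbs_doc, sort_keys=True, indent=2) + "\n")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return report


class LongitudinalRichClubAnalysis:
    """Model object for the two-group, pre/post rich-club analysis.

    Parameters
    ----------
    cohort : Cohort
        Subjects with pre/post (timepoints x regions) series and scores.
    region_table : RegionTable, optional
        Defaults to the packaged 90-region table when the cohort matches it,
        otherwise to an unlabeled table with an empty rich set.
    config : AnalysisConfig, optional
    """

    def __init__(self, cohort: Cohort, region_table: RegionTable = None,
                 config: AnalysisConfig = None):
        self.cohort = cohort
        self.config = config or AnalysisConfig()
        n = cohort.spec.n_regions
        if region_table is None:
            if n == 90:
                region_table = load_region_table()
            else:
                core = cohort.spec.resolved_core()
                rich = np.zeros(n, dtype=bool)
                rich[core] = True
                region_table = RegionTable(
                    names=tuple(f"r{i + 1:03d}" for i in range(n)),
                    subnetwork=tuple("none" for _ in range(n)),
                    rich_club_member=rich,
                )
        if region_table.n_regions != n:
            raise ValueError(
                f"region table has {region_table.n_regions} regions, cohort has {n}"
            )
        self.region_table = region_table

    @classmethod
    def from_manifest(cls, manifest_path, region_table_path=None,
                      config: AnalysisConfig = None) -> "LongitudinalRichClubAnalysis":
        cohort = load_cohort(manifest_path)
        table = load_region_table(region_table_path) if region_table_path else None
        return cls(cohort, region_table=table, config=config)

    # -- fitting ----------------------------------------------------------

    def _fit_group(self, label: str, subjects, group_idx: int) -> GroupResults:
        cfg = self.config
        rich, _ = partition_nodes(self.region_table)
        n = self.region_table.n_regions
        names = self.region_table.names

        raw = {"pre": [], "post": []}
        thresholded = {"pre": [], "post": []}
        glob_rows, rc_rows = [], []
        nodal = {m: {"pre": [], "post": []} for m in NODAL_METRIC_NAMES}
        for s_idx, s in enumerate(subjects):
            for sess_idx, (sess, series) in enumerate((("pre", s.pre), ("post", s.post))):
                rawfc = pearson_fc(series)
                fcm = threshold_fwe(rawfc, alpha=cfg.fwe_alpha, method=cfg.fwe_method)
                raw[sess].append(rawfc)
                thresholded[sess].append(fcm)
                gseed = np.random.SeedSequence([cfg.seed, group_idx, s_idx, sess_idx])
                gm = global_metrics(fcm, mode=cfg.metric_mode, n_null=cfg.n_null,
                                    n_swaps_per_edge=cfg.n_swaps_per_edge, seed=gseed)
                nm = nodal_metrics(fcm, mode=cfg.metric_mode)
                rc = richclub_summary(fcm, rich)
                assert abs(rc.total - gm.overall_strength) < 1e-9 * max(1.0, gm.overall_strength)
                glob_rows.append({
                    "group": label, "subject": s.subject, "session": sess,
                    "overall_strength": gm.overall_strength,
                    "global_efficiency": gm.global_efficiency,
                    "gamma": gm.gamma, "lambda": gm.lambda_, "sigma": gm.sigma,
                })
                rc_rows.append({
                    "group": label, "subject": s.subject, "session": sess,
                    "rich_connectivity": rc.rich_connectivity,
                    "feeder_connectivity": rc.feeder_connectivity,
                    "local_connectivity": rc.local_connectivity,
                })
                for m in NODAL_METRIC_NAMES:
                    nodal[m][sess].append(getattr(nm, m))
            log.info("group=%s subject=%s processed", label, s.subject)

        global_table = pd.DataFrame(glob_rows)
        richclub_table = pd.DataFrame(rc_rows)
        nodal = {m: {sess: np.vstack(v) for sess, v in d.items()}
                 for m, d in nodal.items()}

        def col(df, name):
            pre = df[df.session == "pre"][name].to_numpy()
            post = df[df.session == "post"][name].to_numpy()
            return pre, post

        global_tests = {}
        for name in ("overall_strength", "global_efficiency", "sigma"):
            global_tests[name] = _safe_wilcoxon(*col(global_table, name))
        for name in ("rich_connectivity", "feeder_connectivity", "local_connectivity"):
            global_tests[name] = _safe_wilcoxon(*col(richclub_table, name))

        nodal_tests = {}
        for m in NODAL_METRIC_NAMES:
            p = np.array([
                _safe_wilcoxon(nodal[m]["pre"][:, i], nodal[m]["post"][:, i]).p_value
                for i in range(n)
            ])
            filled = np.where(np.isfinite(p), p, 1.0)  # untestable nodes: no evidence
            reject, p_fdr = bh_fdr(filled, q=cfg.fdr_q)
            nodal_tests[m] = {"p": filled, "p_fdr": p_fdr, "reject": reject}

        nbs_seed = np.random.SeedSequence([cfg.seed, 7001 + group_idx])
        if cfg.nbs_on_raw:
            pre_mats = [r.r for r in raw["pre"]]
            post_mats = [r.r for r in raw["post"]]
        else:
            pre_mats = [f.w for f in thresholded["pre"]]
            post_mats = [f.w for f in thresholded["post"]]
        nbs_res = nbs_paired(pre_mats, post_mats, threshold=cfg.nbs_threshold,
                             n_permutations=cfg.nbs_permutations,
                             direction=cfg.nbs_direction, seed=nbs_seed)
        log.info("group=%s NBS done: %d component(s)", label, len(nbs_res.components))
        return GroupResults(
            label=label, subjects=[s.subject for s in subjects],
            global_table=global_table, richclub_table=richclub_table,
            nodal=nodal, global_tests=global_tests, nodal_tests=nodal_tests,
            nbs=nbs_res,
        )

    def fit(self) -> RichClubResults:
        cfg = self.config
        groups, skipped = {}, {}
        for g_idx, label in enumerate((TREATMENT, CONTROL)):
            subjects = self.cohort.group(label)
            if not subjects:
                continue
            if len(subjects) < 3:
                skipped[label] = f"only {len(subjects)} subject(s); need >= 3"
                continue
            groups[label] = self._fit_group(label, subjects, g_idx)

        spearman_results = {}
        if TREATMENT in groups:
            g = groups[TREATMENT]
            rc = g.richclub_table
            change = (
                rc[rc.session == "post"]["rich_connectivity"].to_numpy()
                - rc[rc.session == "pre"]["rich_connectivity"].to_numpy()
            )
            subjects = self.cohort.group(TREATMENT)
            scales = sorted(subjects[0].scores) if subjects and subjects[0].scores else []
            for scale in scales:
                dscore = np.array([s.scores[scale][1] - s.scores[scale][0]
                                   for s in subjects])
                try:
                    spearman_results[scale] = spearman(change, dscore)
                except ValueError:
                    spearman_results[scale] = StatResult(
                        float("nan"), float("nan"), len(subjects), "undefined")
        return RichClubResults(config=cfg, region_table=self.region_table,
                               groups=groups, spearman=spearman_results,
                               skipped=skipped)


def run_longitudinal_analysis(config: AnalysisConfig) -> RichClubResults:
    """File-driven entry point: load the cohort manifest, fit, write outputs."""
    if not config.manifest:
        raise ValueError("config.manifest is required")
    model = LongitudinalRichClubAnalysis.from_manifest(
        config.manifest, region_table_path=config.region_table, config=config
    )
    results = model.fit()
    if config.output_dir:
        results.save(config.output_dir)
    return results
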