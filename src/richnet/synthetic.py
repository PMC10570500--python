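"""Synthetic multi-session cohorts of ROI time series with a planted rich-club core.

The generator emulates the statistical structure of nuisance-cleaned,
band-limited resting-state ROI time series that the downstream correlation
network analysis assumes: stationary multivariate Gaussian signals whose target
correlation matrix has a densely connected core block (the rich-club regions)
sitting on a weakly correlated periphery.  Two sessions (pre/post) are produced
per subject for two groups; for the treatment group only, every core-core
correlation is raised by ``treatment_delta`` in the post session.  Temporal
smoothness mimicking band-pass filtered BOLD is obtained by passing the samples
through an AR(1) filter (the same filter for every region, so the cross-regional
correlation structure is preserved) and re-standardising.

Symptom scores are planted with a monotone link to connectivity change: for a
treatment subject, post = pre + slope x (realised core-block mean-correlation
change) + noise, so a larger realised rich-club increase yields a larger score
drop when the slope is negative; controls get pre + noise.

Defaults mirror the target study's conditions: 90 regions, 139 timepoints
(6 min at TR 2.5 s minus 5 discarded volumes), 14 treatment and 15 no-treatment
subjects, and a MADRS-like primary scale (pre 28.7 +/- 2.6) whose slope of -87
turns the planted +0.15 core change into a ~13-point drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import load_region_table

__all__ = [
    "ScoreScale",
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "build_target_correlation",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

TREATMENT = "treatment"
CONTROL = "no-treatment"


@dataclass(frozen=True)
class ScoreScale:
    """One clinical rating scale: pre-session distribution and planted link."""

    pre_mean: float
    pre_sd: float
    slope: float       # score change per unit of realised core-correlation change
    noise_sd: float


def _default_scales():
    return {
        "madrs": ScoreScale(pre_mean=28.7, pre_sd=2.6, slope=-87.0, noise_sd=1.5),
        "mcsds": ScoreScale(pre_mean=10.6, pre_sd=1.7, slope=-10.0, noise_sd=0.8),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``core_nodes`` defaults to the packaged 14-region rich club when
    ``n_regions`` is 90, otherwise to the first ``min(14, n_regions)`` nodes.
    """

    n_regions: int = 90
    n_timepoints: int = 139
    n_subjects_treat: int = 14
    n_subjects_control: int = 15
    base_corr_periphery: float = 0.1
    base_corr_core: float = 0.35
    treatment_delta: float = 0.15
    ar_coefficient: float = 0.4
    scales: dict = field(default_factory=_default_scales)
    core_nodes: tuple = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.base_corr_periphery < 1.0 and 0.0 <= self.base_corr_core < 1.0):
            raise ValueError("base correlations must lie in [0, 1)")
        if self.base_corr_core + self.treatment_delta >= 1.0:
            raise ValueError("base_corr_core + treatment_delta must stay below 1")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.n_timepoints <= self.n_regions:
            warnings.warn(
                "n_timepoints <= n_regions: sample correlation matrices will be "
                "rank-deficient and unstable",
                stacklevel=2,
            )

    def resolved_core(self) -> np.ndarray:
        if self.core_nodes is not None:
            core = np.asarray(sorted(int(i) for i in self.core_nodes))
            if core.size and (core[0] < 0 or core[-1] >= self.n_regions):
                raise ValueError("core_nodes out of range")
            return core
        if self.n_regions == 90:
            return load_region_table().rich_indices
        return np.arange(min(14, self.n_regions))


@dataclass
class SubjectRecord:
    subject: str
    group: str
    pre: np.ndarray    # timepoints x regions
    post: np.ndarray
    scores: dict       # scale name -> (pre, post)
    core_change: float  # realised core-block mean sample-correlation change


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list

    def group(self, label: str):
        return [s for s in self.subjects if s.group == label]


def _repair_psd(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero, then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(c)
    if vals[0] >= 0:
        return c
    vals = np.clip(vals, 0.0, None)
    c = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def build_target_correlation(spec: CohortSpec, session: str, group: str) -> np.ndarray:
    """Target correlation matrix for one session/group cell.

    Core-core entries sit at ``base_corr_core`` (plus ``treatment_delta`` for
    the treatment group's post session); all other off-diagonal entries at
    ``base_corr_periphery``.  The result is symmetric, positive semidefinite
    (repaired by eigenvalue clipping when needed) with unit diagonal.
    """
    if session not in ("pre", "post"):
        raise ValueError(f"unknown session {session!r}")
    if group not in (TREATMENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    n = spec.n_regions
    c = np.full((n, n), spec.base_corr_periphery)
    core = spec.resolved_core()
    core_level = spec.base_corr_core
    if session == "post" and group == TREATMENT:
        core_level += spec.treatment_delta
    c[np.ix_(core, core)] = core_level
    np.fill_diagonal(c, 1.0)
    return _repair_psd(c)


def _factor(c: np.ndarray) -> np.ndarray:
    """Square-root factor L with L @ L.T = c (eigen-based; tolerates PSD)."""
    vals, vecs = np.linalg.eigh(c)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _draw_series(rng, factor, t, phi):
    z = rng.standard_normal((t, factor.shape[0]))
    x = z @ factor.T
    if phi > 0:
        x = signal.lfilter([1.0], [1.0, -phi], x, axis=0)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _core_block_mean(series, core):
    r = np.corrcoef(series, rowvar=False)
    block = r[np.ix_(core, core)]
    iu = np.triu_indices(len(core), 1)
    return float(block[iu].mean())


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one full cohort; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    core = spec.resolved_core()
    factors = {
        (sess, grp): _factor(build_target_correlation(spec, sess, grp))
        for sess in ("pre", "post")
        for grp in (TREATMENT, CONTROL)
    }
    subjects = []
    plan = [(TREATMENT, spec.n_subjects_treat), (CONTROL, spec.n_subjects_control)]
    for grp, count in plan:
        tag = "t" if grp == TREATMENT else "c"
        for k in range(count):
            pre = _draw_series(rng, factors[("pre", grp)], spec.n_timepoints, spec.ar_coefficient)
            post = _draw_series(rng, factors[("post", grp)], spec.n_timepoints, spec.ar_coefficient)
            change = _core_block_mean(post, core) - _core_block_mean(pre, core) if core.size > 1 else 0.0
            scores = {}
            for name, scale in spec.scales.items():
                s_pre = rng.normal(scale.pre_mean, scale.pre_sd)
                noise = rng.normal(0.0, scale.noise_sd)
                if grp == TREATMENT:
                    s_post = s_pre + scale.slope * change + noise
                else:
                    s_post = s_pre + noise
                scores[name] = (float(s_pre), float(s_post))
            subjects.append(
                SubjectRecord(
                    subject=f"sub-{tag}{k + 1:02d}",
                    group=grp,
                    pre=pre,
                    post=post,
                    scores=scores,
                    core_change=change,
                )
            )
    return Cohort(spec=spec, subjects=subjects)


def write_cohort(cohort: Cohort, outdir, region_names=None) -> Path:
    """Write per-subject/session series TSVs plus a cohort manifest TSV.

    Returns the manifest path.  Column headers are region names (generated
    ``r001``.. when none are given and the region count is not 90; the packaged
    AAL labels when it is).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = cohort.spec.n_regions
    if region_names is None:
        if n == 90:
            region_names = list(load_region_table().names)
        else:
            region_names = [f"r{i + 1:03d}" for i in range(n)]
    rows = []
    for s in cohort.subjects:
        paths = {}
        for sess, series in (("pre", s.pre), ("post", s.post)):
            p = outdir / f"{s.subject}_{sess}.tsv"
            pd.DataFrame(series, columns=region_names).to_csv(
                p, sep="\t", index=False, float_format="%.6f"
            )
            paths[sess] = p.name
        row = {"subject": s.subject, "group": s.group,
               "pre_path": paths["pre"], "post_path": paths["post"]}
        for name, (a, b) in s.scores.items():
            row[f"{name}_pre"] = round(a, 4)
            row[f"{name}_post"] = round(b, 4)
        rows.append(row)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (series re-read from TSV)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t")
    score_names = sorted(
        {c[:-4] for c in df.columns if c.endswith("_pre") and c != "pre_path"}
    )
    subjects = []
    n_regions = None
    t = None
    for _, row in df.iterrows():
        pre = pd.read_csv(base / row["pre_path"], sep="\t").to_numpy(float)
        post = pd.read_csv(base / row["post_path"], sep="\t").to_numpy(float)
        if n_regions is None:
            n_regions, t = pre.shape[1], pre.shape[0]
        if pre.shape != (t, n_regions) or post.shape != (t, n_regions):
            raise ValueError(f"inconsistent series dimensions for {row['subject']}")
        scores = {
            name: (float(row[f"{name}_pre"]), float(row[f"{name}_post"]))
            for name in score_names
        }
        subjects.append(
            SubjectRecord(
                subject=str(row["subject"]), group=str(row["group"]),
                pre=pre, post=post, scores=scores, core_change=float("nan"),
            )
        )
    spec = replace(
        CohortSpec(n_regions=n_regions, n_timepoints=t,
                   n_subjects_treat=sum(s.group == TREATMENT for s in subjects),
                   n_subjects_control=sum(s.group == CONTROL for s in subjects)),
    )
    return Cohort(spec=spec, subjects=subjects)
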