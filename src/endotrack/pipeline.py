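"""End-to-end orchestration: simulate/load -> quantify -> compare.

The pipeline is deterministic given its configuration and seed: output
tables (and the run log, which carries no timestamps) are byte-identical
across re-runs. Quantification does not depend on whether statistics
are requested, and the filter audit satisfies

    n input tracks = n included + sum over reasons of n excluded

for every animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import caliber as caliber_mod
from . import group_stats, kinematics, simulate
from .io import read_track_table, summaries_to_frame, write_track_table
from .model import AnimalSummary, Cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "comparisons_to_frame"]

STAT_METRICS = [
    "mean_speed_um_s",
    "max_speed_um_s",
    "pct_time_paused",
    "pct_pausing_endosomes",
    "caliber_um",
]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``preset`` must be set. ``force``
    overrides the normality gate ("parametric" / "nonparametric").
    """

    input_path: Optional[str] = None
    preset: Optional[str] = None
    eps_um: float = kinematics.DEFAULT_EPS_UM
    hist_bin_width: float = 0.2
    control: Optional[str] = None
    paired: bool = False
    alpha: float = 0.05
    force: Optional[str] = None
    dunn_adjustment: str = "bonferroni"
    blind: bool = False
    out_dir: Optional[str] = None
    seed: int = 0
    write_steps: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("set exactly one of input_path or preset")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.eps_um < 0:
            raise ValueError("eps_um must be >= 0")
        if self.force not in (None, "parametric", "nonparametric"):
            raise ValueError("force must be None, 'parametric' or 'nonparametric'")


@dataclass
class PipelineResult:
    cohort: Cohort
    summaries: list
    comparisons: list
    audit: dict  # animal_id -> {"included": n, "too-short": n, ...}
    blinding_map: Optional[dict] = None
    out_dir: Optional[Path] = None


def _audit(all_metrics) -> dict:
    audit: dict[str, dict[str, int]] = {}
    for m in all_metrics:
        a = audit.setdefault(
            m.animal_id,
            {"input": 0, "included": 0, **{r: 0 for r in kinematics.EXCLUSION_REASONS}},
        )
        a["input"] += 1
        if m.included:
            a["included"] += 1
        else:
            a[m.exclusion_reason] += 1
    return audit


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        base = {
            "metric": c.metric,
            "design": c.design,
            "test": c.test_used,
            "omnibus_statistic": c.statistic,
            "omnibus_p": c.pvalue,
            "alpha": c.alpha,
        }
        if not c.comparisons:
            rows.append({**base, "contrast": "", "contrast_statistic": np.nan,
                         "p_unadjusted": np.nan, "p_adjusted": np.nan,
                         "significant": False})
        for ct in c.comparisons:
            rows.append(
                {
                    **base,
                    "contrast": ct.name,
                    "contrast_statistic": ct.statistic,
                    "p_unadjusted": (
                        np.nan if ct.p_unadjusted is None else ct.p_unadjusted
                    ),
                    "p_adjusted": ct.p_adjusted,
                    "significant": bool(ct.p_adjusted < c.alpha),
                }
            )
    cols = ["metric", "design", "test", "omnibus_statistic", "omnibus_p",
            "alpha", "contrast", "contrast_statistic", "p_unadjusted",
            "p_adjusted", "significant"]
    return pd.DataFrame(rows, columns=cols)


def _blind_groups(groups: list[str], seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed ^ 0x5D1E)
    order = rng.permutation(len(groups))
    return {g: f"group_{order[i] + 1:02d}" for i, g in enumerate(sorted(groups))}


def quantify(cohort: Cohort, config: PipelineConfig):
    """Quantification stage: summaries (incl. caliber), metrics, steps."""
    summaries, all_metrics, steps = kinematics.summarize_cohort(
        cohort,
        eps=config.eps_um,
        bin_width=config.hist_bin_width,
        collect_steps=config.write_steps,
    )
    _, animal_cal = caliber_mod.cohort_calibers(cohort)
    for s in summaries:
        s.caliber_um = animal_cal.get((s.animal_id, s.group))
    return summaries, all_metrics, steps


def compare(
    summaries: list[AnimalSummary], config: PipelineConfig
) -> list[group_stats.GroupComparisonResult]:
    """Statistics stage on per-animal summaries, one result per metric."""
    df = summaries_to_frame(summaries)
    groups = sorted(df["group"].unique())
    results = []
    for metric in STAT_METRICS:
        sub = df[["animal_id", "group", metric]].dropna(subset=[metric])
        present = [g for g in groups if (sub["group"] == g).any()]
        if len(present) < 2:
            continue
        if config.paired and len(present) == 2:
            wide = sub.pivot(index="animal_id", columns="group", values=metric).dropna()
            res = group_stats.compare_two_paired(
                wide[present[0]].to_numpy(),
                wide[present[1]].to_numpy(),
                metric=metric,
                labels=(present[0], present[1]),
            )
        elif len(present) == 2:
            res = group_stats.compare_two_independent(
                sub.loc[sub["group"] == present[0], metric].to_numpy(),
                sub.loc[sub["group"] == present[1], metric].to_numpy(),
                metric=metric,
                labels=(present[0], present[1]),
                force=config.force,
                alpha=config.alpha,
            )
        else:
            res = group_stats.compare_vs_control(
                {g: sub.loc[sub["group"] == g, metric].to_numpy() for g in present},
                control=config.control,
                metric=metric,
                force=config.force,
                dunn_adjustment=config.dunn_adjustment,
                alpha=config.alpha,
                rng=np.random.default_rng(config.seed ^ 0xD0E7),
            )
        results.append(res)
    return results


def _unblind(results, inverse: dict[str, str]):
    for res in results:
        res.normality = {inverse.get(g, g): v for g, v in res.normality.items()}
        for ct in res.comparisons:
            for blinded, real in inverse.items():
                ct.name = ct.name.replace(blinded, real)
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/load -> quantify -> compare and write the report bundle."""
    config.validate()
    log_lines: list[str] = []

    # ---- stage: input -------------------------------------------------
    sim_params = None
    if config.preset is not None:
        sim_params = simulate.preset_cohorts(config.preset, seed=config.seed)
        cohort, _truth = simulate.simulate_cohort(sim_params)
        log_lines.append(f"input: preset {config.preset!r} seed={config.seed}")
        if config.paired != cohort.paired:
            config.paired = cohort.paired
    else:
        cohort = read_track_table(config.input_path, paired=config.paired)
        log_lines.append(f"input: track table {config.input_path}")
    groups = cohort.groups
    if config.control is not None and config.control not in groups:
        raise ValueError(
            f"control group {config.control!r} not found among groups {groups}"
        )
    if len(groups) > 2 and config.control is None:
        raise ValueError(">2 groups require a control label for the comparisons")

    # ---- stage: quantify ----------------------------------------------
    summaries, all_metrics, steps = quantify(cohort, config)
    audit = _audit(all_metrics)
    for animal in sorted(audit):
        a = audit[animal]
        log_lines.append(
            f"filter {animal}: input={a['input']} included={a['included']} "
            + " ".join(f"{r}={a[r]}" for r in kinematics.EXCLUSION_REASONS)
        )

    # ---- stage: compare -----------------------------------------------
    blinding_map = None
    stats_summaries = summaries
    stats_config = config
    if config.blind:
        blinding_map = _blind_groups(groups, config.seed)
        inverse = {v: k for k, v in blinding_map.items()}
        import copy

        stats_summaries = copy.deepcopy(summaries)
        for s in stats_summaries:
            s.group = blinding_map[s.group]
        stats_config = PipelineConfig(**{**asdict(config)})
        if config.control is not None:
            stats_config.control = blinding_map[config.control]
        log_lines.append("blinding: group labels shuffled before statistics")
    comparisons = compare(stats_summaries, stats_config)
    if blinding_map:
        comparisons = _unblind(comparisons, inverse)
    for res in comparisons:
        log_lines.append(
            f"compare {res.metric}: {res.test_used} omnibus_p={res.pvalue:.6g}"
        )

    # ---- stage: write -------------------------------------------------
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if sim_params is not None:
            write_track_table(cohort, out_dir / "tracks.csv")
            with open(out_dir / "sim_params.yaml", "w") as fh:
                yaml.safe_dump(simulate.params_to_dict(sim_params), fh,
                               sort_keys=True)
        summaries_to_frame(summaries).to_csv(
            out_dir / "summary.csv", index=False, lineterminator="\n"
        )
        if steps is not None:
            steps.to_csv(out_dir / "steps.csv", index=False, lineterminator="\n")
        _write_histograms(summaries, out_dir)
        comparisons_to_frame(comparisons).to_csv(
            out_dir / "comparisons.csv", index=False, lineterminator="\n"
        )
        with open(out_dir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return PipelineResult(
        cohort=cohort,
        summaries=summaries,
        comparisons=comparisons,
        audit=audit,
        blinding_map=blinding_map,
        out_dir=out_dir,
    )


def _write_histograms(summaries, out_dir: Path) -> None:
    rows = []
    for s in summaries:
        if s.hist is None:
            continue
        for k, pct in enumerate(s.hist):
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "bin_left_um_s": k * s.hist_bin_width,
                    "pct": pct,
                }
            )
    df = pd.DataFrame(rows, columns=["animal_id", "group", "bin_left_um_s", "pct"])
    df.to_csv(out_dir / "histogram.csv", index=False, lineterminator="\n")
    if len(df):
        rows_g = []
        for g, sub in df.groupby("group", sort=True):
            by_animal = [
                a_sub.set_index("bin_left_um_s")["pct"]
                for _, a_sub in sub.groupby("animal_id", sort=True)
            ]
            edges = sorted({e for s_ in by_animal for e in s_.index})
            mat = np.zeros((len(by_animal), len(edges)))
            for i, s_ in enumerate(by_animal):
                for j, e in enumerate(edges):
                    mat[i, j] = s_.get(e, 0.0)
            mean = mat.mean(axis=0)
            sem = (
                mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
                if mat.shape[0] > 1
                else np.zeros(len(edges))
            )
            for j, e in enumerate(edges):
                rows_g.append(
                    {"group": g, "bin_left_um_s": e, "mean_pct": mean[j],
                     "sem_pct": sem[j]}
                )
        pd.DataFrame(rows_g).to_csv(
            out_dir / "group_histogram.csv", index=False, lineterminator="\n"
        )
    else:
        pd.DataFrame(
            columns=["group", "bin_left_um_s", "mean_pct", "sem_pct"]
        ).to_csv(out_dir / "group_histogram.csv", index=False, lineterminator="\n")
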