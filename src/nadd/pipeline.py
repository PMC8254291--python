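"""End-to-end pipeline: curate -> pairs -> cycles -> summaries -> reports.

Each assay is processed independently; every run directory receives the
resolved configuration, the per-step curation report, the matched-pair and
cycle tables, the supplementary-style per-compound table, the assay summary
and histogram data (observed ddpAct density against the theoretical pure-noise
density). All randomness flows from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import curation, mmp
from .curation import CurationConfig, CuratedAssay, FilterReport


@dataclass
class PipelineConfig:
    dataset_label: str = "run"
    sigma_exp: float = 0.5
    significance_rule: str = "any_cycle"
    curation: CurationConfig = field(default_factory=CurationConfig)
    max_variable_fraction: float = mmp.DEFAULT_MAX_VARIABLE_FRACTION
    seed: int = 0
    histogram_bins: int = 80
    histogram_range: tuple[float, float] = (-5.0, 5.0)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o).__name__)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclass
class AssayResult:
    assay_id: str
    report: FilterReport
    assay: CuratedAssay | None
    pairs: list[mmp.MatchedPair] = field(default_factory=list)
    cycles: list[cyc.DoubleTransformationCycle] = field(default_factory=list)
    profiles: list[cyc.CompoundNAProfile] = field(default_factory=list)
    summary: cyc.AssayNASummary | None = None


def analyze_assay(
    records: Sequence[curation.ActivityRecord],
    config: PipelineConfig,
) -> AssayResult:
    """Run curation, MMP indexing, cycle assembly and NA summaries for one assay."""
    assay, report = curation.curate_assay(records, config.curation)
    result = AssayResult(report.assay_id, report, assay)
    if assay is None:
        return result
    noise = cyc.NoiseModel(config.sigma_exp)
    structures = assay.smiles_by_id
    result.pairs = mmp.index_pairs(structures, config.max_variable_fraction)
    result.cycles = cyc.assemble_cycles(result.pairs, assay.pact_by_id)
    result.profiles = cyc.compound_profiles(result.cycles, noise,
                                            config.significance_rule)
    result.summary = cyc.assay_summary(assay.assay_id, result.cycles,
                                       len(assay), noise, result.profiles)
    return result


def run_pipeline(
    records_by_assay: Mapping[str, Sequence[curation.ActivityRecord]],
    config: PipelineConfig,
    out_dir: str | Path,
) -> Path:
    """Process every assay independently and write all tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    reports, curated, pair_frames, cycle_frames, prof_frames, summaries = \
        [], [], [], [], [], []
    for assay_id in sorted(records_by_assay):
        res = analyze_assay(records_by_assay[assay_id], config)
        reports.append(res.report.to_frame())
        if res.assay is None:
            continue
        curated.append(res.assay.to_frame().assign(assay_id=assay_id))
        pair_frames.append(mmp.pairs_to_frame(res.pairs).assign(assay_id=assay_id))
        cycle_frames.append(cyc.cycles_to_frame(res.cycles).assign(assay_id=assay_id))
        prof_frames.append(
            cyc.profiles_to_frame(
                res.profiles, res.assay.smiles_by_id, res.assay.pact_by_id,
                all_compounds=sorted(res.assay.pact_by_id),
            ).assign(assay_id=assay_id)
        )
        summaries.append(summary_row(res.summary))

    def write(frames, name, columns):
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=columns))
        df.to_csv(out / name, index=False, float_format="%.8g")

    write(reports, "filter_report.csv", ["step", "records_in", "records_out", "assay_id"])
    write(curated, "curated.csv", ["compound_id", "smiles", "pact", "assay_id"])
    write(pair_frames, "pairs.csv",
          ["compound_a", "compound_b", "context", "transformation_from",
           "transformation_to", "assay_id"])
    write(cycle_frames, "cycles.csv",
          ["c1", "c2", "c3", "c4", "transformation_a", "transformation_b",
           "pact_1", "pact_2", "pact_3", "pact_4", "nonadditivity", "assay_id"])
    write(prof_frames, "compound_profiles.csv",
          ["compound_id", "smiles", "pact", "n_cycles", "na_max_abs", "na_mean_abs",
           "mean_shift", "std_shift", "ci_low", "ci_high", "significant", "assay_id"])
    pd.DataFrame(summaries).to_csv(out / "assay_summary.csv", index=False)

    # histogram data: observed ddpAct density vs theoretical noise density
    if cycle_frames:
        na = pd.concat(cycle_frames)["nonadditivity"].to_numpy()
        hist = histogram_table(na, config)
        hist.to_csv(out / "na_histogram.csv", index=False)
    return out


def summary_row(s: cyc.AssayNASummary) -> dict:
    d = dataclasses.asdict(s)
    d["frac_cycles_significant"] = s.frac_cycles_significant
    d["frac_cycles_strong"] = s.frac_cycles_strong
    return d


def histogram_table(na_values: np.ndarray, config: PipelineConfig) -> pd.DataFrame:
    """Normalized-density histogram of observed ddpAct with the noise overlay."""
    lo, hi = config.histogram_range
    counts, edges = np.histogram(na_values, bins=config.histogram_bins,
                                 range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    theo = cyc.theoretical_noise_density(config.sigma_exp, centers)
    return pd.DataFrame({
        "bin_center": centers,
        "observed_density": counts,
        "theoretical_noise_density": theo,
    })


def report_run(run_dir: str | Path, render_plots: bool = False) -> dict[str, pd.DataFrame]:
    """Load a finished run's tables; optionally render figures next to them.

    Returns the histogram data, the per-compound shift table with its 95% CI
    band, and the assay summary table. Plots are optional so downstream
    checks assert on numbers, not pixels.
    """
    run = Path(run_dir)
    tables = {
        "histogram": pd.read_csv(run / "na_histogram.csv")
        if (run / "na_histogram.csv").exists() else pd.DataFrame(),
        "profiles": pd.read_csv(run / "compound_profiles.csv"),
        "summary": pd.read_csv(run / "assay_summary.csv"),
    }
    if render_plots:
        _render(run, tables)
    return tables


def _render(run: Path, tables: dict[str, pd.DataFrame]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(tables["histogram"]):
        fig, ax = plt.subplots(figsize=(6, 4))
        h = tables["histogram"]
        ax.bar(h["bin_center"], h["observed_density"],
               width=h["bin_center"].diff().median(), alpha=0.6, label="observed")
        ax.plot(h["bin_center"], h["theoretical_noise_density"], "k-",
                label="noise model")
        ax.set_xlabel(r"$\Delta\Delta$pAct (log units)")
        ax.set_ylabel("density")
        ax.legend()
        fig.savefig(run / "na_histogram.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    prof = tables["profiles"].dropna(subset=["n_cycles"])
    if len(prof):
        prof = prof.sort_values("mean_shift").reset_index(drop=True)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(range(len(prof)), prof["mean_shift"], yerr=prof["std_shift"],
                    fmt=".", ms=3, elinewidth=0.5)
        ax.plot(range(len(prof)), prof["ci_high"], "r--", lw=0.8, label="95% null band")
        ax.plot(range(len(prof)), prof["ci_low"], "r--", lw=0.8)
        ax.set_xlabel("compound (sorted)")
        ax.set_ylabel("mean additivity shift (log units)")
        ax.legend()
        fig.savefig(run / "compound_shifts.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
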