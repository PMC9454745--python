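"""Report assembly: chain the analysis stages into one JSON/CSV bundle.

The bundle reproduces the study's result surface on a (synthetic or real)
cohort: frequency-response tables with per-frequency adjusted p values,
the main-sequence slope comparison, the learning table, and the
spike-metric comparisons.  Every report carries the master seed and a
SHA-256 hash of the generating config so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import gaze, learning, main_sequence, spikes, stats
from .io import read_manifest, read_spike_file
from .types import ValidationError

REPORT_SCHEMA_VERSION = 1

_REQUIRED_SECTIONS = ("meta", "frequency_response", "main_sequence",
                      "learning", "spike_metrics")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def validate_report(report: dict) -> None:
    """Schema check: required sections and key fields must be present."""
    missing = [s for s in _REQUIRED_SECTIONS if s not in report]
    if missing:
        raise ValidationError(f"report missing sections: {missing}")
    meta = report["meta"]
    for key in ("seed", "config_sha256", "schema_version"):
        if key not in meta:
            raise ValidationError(f"report meta missing {key!r}")
    ms = report["main_sequence"]
    if ms is not None:
        for key in ("groups", "comparison"):
            if key not in ms:
                raise ValidationError(f"main_sequence section missing {key!r}")


def _anova_dict(res: stats.AnovaResult) -> dict:
    return dict(between=asdict(res.between), within=asdict(res.within),
                interaction=asdict(res.interaction),
                posthoc=res.posthoc.to_dict(orient="records"))


def _maybe_anova(table: pd.DataFrame, dv: str, between: str = "genotype",
                 within: str = "frequency_hz",
                 subject: str = "animal") -> dict | None:
    """Mixed ANOVA if the design supports it (>= 2 groups of >= 2 subjects,
    >= 2 within levels), else None — small fixtures skip inference."""
    if table[within].nunique() < 2 or table[between].nunique() != 2:
        return None
    if (table.groupby(between, observed=True)[subject].nunique() < 2).any():
        return None
    return _anova_dict(stats.mixed_anova(table, dv=dv, between=between,
                                         within=within, subject=subject))


def build_report(dataset_dir: str | Path, seed: int, config: dict,
                 desaccade_opts: gaze.DesaccadeOptions | None = None) -> dict:
    """Run every analysis stage on an on-disk cohort and assemble the bundle.

    Stages that have no corresponding recordings in the manifest (e.g. no
    pre/post pairs) raise, since a complete bundle is the contract; the
    caller controls scope through the manifest.
    """
    dataset_dir = Path(dataset_dir)
    manifest = read_manifest(dataset_dir / "manifest.json")
    bonf_m = int(config.get("stats", {}).get("bonferroni_comparisons", 5))

    # --- frequency response (gain/phase per condition) ------------------
    fr_table, fr_summary = gaze.frequency_response(dataset_dir, manifest,
                                                   opts=desaccade_opts)
    fr_anova = {}
    for condition in sorted(fr_table["condition"].unique()):
        sub = fr_table[fr_table["condition"] == condition]
        dvs = {dv: _maybe_anova(sub, dv=dv) for dv in ("gain", "phase")}
        fr_anova[condition] = {k: v for k, v in dvs.items() if v is not None}

    # --- quick phases / main sequence ------------------------------------
    qp = gaze.collect_quick_phases(dataset_dir, manifest, opts=desaccade_opts)
    ms_section = None
    genotypes = sorted(qp["genotype"].unique()) if len(qp) else []
    if len(genotypes) == 2:
        ga = qp[qp["genotype"] == genotypes[0]]
        gb = qp[qp["genotype"] == genotypes[1]]
        fits = {g: main_sequence.fit_main_sequence(
                    qp.loc[qp["genotype"] == g, "amplitude_deg"],
                    qp.loc[qp["genotype"] == g, "peak_vel_dps"])
                for g in genotypes}
        comp = main_sequence.compare_slopes(
            ga["amplitude_deg"], ga["peak_vel_dps"],
            gb["amplitude_deg"], gb["peak_vel_dps"])
        ms_section = dict(
            groups={g: asdict(f) for g, f in fits.items()},
            comparison=asdict(comp))

    # --- learning ---------------------------------------------------------
    learn_section = None
    if any(e["condition"] in ("pre", "post") for e in manifest):
        lt, ls = learning.learning_table(dataset_dir, manifest,
                                         opts=desaccade_opts)
        learn_anova = _maybe_anova(lt, dv="pct_change")
        mw_per_freq = {}
        for freq in sorted(lt["frequency_hz"].unique()):
            sub = lt[lt["frequency_hz"] == freq]
            gs = sorted(sub["genotype"].unique())
            if len(gs) == 2:
                mw = stats.mann_whitney(
                    sub.loc[sub["genotype"] == gs[0], "pct_change"],
                    sub.loc[sub["genotype"] == gs[1], "pct_change"])
                d = asdict(mw)
                d["p_adj"] = stats.bonferroni(mw.p_two_sided, bonf_m)
                mw_per_freq[str(freq)] = d
        learn_section = dict(table=lt.to_dict(orient="records"),
                             summary=ls.to_dict(orient="records"),
                             anova=learn_anova, mann_whitney=mw_per_freq)

    # --- spike metrics ----------------------------------------------------
    spike_section = None
    spike_entries = [e for e in manifest if e["file"].endswith(".spk")]
    if spike_entries:
        trains = []
        sp_dur = config.get("spikes", {}).get("duration_s")
        for e in spike_entries:
            trains.append(read_spike_file(
                dataset_dir / e["file"], duration=sp_dur,
                metadata=dict(cell_id=e["animal_id"], genotype=e["genotype"],
                              state=e.get("state", ""))))
        sp_table, sp_summary = spikes.population_summary(trains)
        comparisons = {}
        for state in sorted(sp_table["state"].unique()):
            sub = sp_table[sp_table["state"] == state]
            gs = sorted(sub["genotype"].unique())
            if len(gs) != 2:
                continue
            comparisons[state] = {
                metric: asdict(stats.mann_whitney(
                    sub.loc[sub["genotype"] == gs[0], metric],
                    sub.loc[sub["genotype"] == gs[1], metric]))
                for metric in ("rate_sps", "cv", "cv2")}
        spike_section = dict(table=sp_table.to_dict(orient="records"),
                             summary=sp_summary.to_dict(orient="records"),
                             mann_whitney=comparisons)

    report = dict(
        meta=dict(seed=int(seed), config_sha256=config_hash(config),
                  schema_version=REPORT_SCHEMA_VERSION,
                  bonferroni_comparisons=bonf_m),
        frequency_response=dict(table=fr_table.to_dict(orient="records"),
                                summary=fr_summary.to_dict(orient="records"),
                                anova=fr_anova),
        main_sequence=ms_section,
        learning=learn_section,
        spike_metrics=spike_section,
    )
    report = _round_floats(report)
    validate_report(report)
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write ``report.json`` plus a flat ``stats_tables.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
    rows = []
    for condition, dvs in report["frequency_response"]["anova"].items():
        for dv, res in dvs.items():
            for effect in ("between", "within", "interaction"):
                e = res[effect]
                rows.append(dict(stage="frequency_response",
                                 condition=condition, dv=dv, test="anova",
                                 effect=effect, stat=e["f_stat"],
                                 p=e["p_value"]))
            for row in res["posthoc"]:
                rows.append(dict(stage="frequency_response",
                                 condition=condition, dv=dv, test="posthoc_t",
                                 effect=f"frequency={row['frequency_hz']}",
                                 stat=row["t_stat"], p=row["p_adj"]))
    ms = report["main_sequence"]
    if ms:
        comp = ms["comparison"]
        rows.append(dict(stage="main_sequence", condition="", dv="slope",
                         test="extra_ss_F", effect="slope_equality",
                         stat=comp["f_stat"], p=comp["p_value"]))
    if report["learning"]:
        for freq, mw in report["learning"]["mann_whitney"].items():
            rows.append(dict(stage="learning", condition="", dv="pct_change",
                             test="mann_whitney", effect=f"frequency={freq}",
                             stat=mw["u_stat"], p=mw["p_two_sided"]))
    if report["spike_metrics"]:
        for state, metrics in report["spike_metrics"]["mann_whitney"].items():
            for metric, mw in metrics.items():
                rows.append(dict(stage="spike_metrics", condition=state,
                                 dv=metric, test="mann_whitney",
                                 effect="genotype", stat=mw["u_stat"],
                                 p=mw["p_two_sided"]))
    pd.DataFrame(rows).to_csv(out / "stats_tables.csv", index=False,
                              float_format="%.10g", lineterminator="\n")


def run_all(config: dict, seed: int, out_dir: str | Path) -> dict:
    """simulate → analyze → report, returning the report dict."""
    from .synthetic import gen_cohort

    out = Path(out_dir)
    data_dir = out / "data"
    gen_cohort(config, seed, data_dir)
    report = build_report(data_dir, seed, config)
    write_report(report, out)
    return report
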