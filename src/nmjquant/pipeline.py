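"""Pipeline orchestration: simulate -> (render -> detect) -> estimate -> compare.

Each stage is a pure function of (config, seed) and writes tab-separated
tables plus a run-metadata file, so a run is fully reproducible and every
exclusion (rejected recording, skipped estimator, statistical branch) is
logged.

Two modes share all downstream code: ``amplitude_only`` works at the
amplitude-table level (fast; the statistical workhorse) while
``full_trace`` additionally renders the spontaneous and quantal-content
sweeps to continuous current traces and re-derives those amplitudes through
noise estimation and event detection.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import qtrc
from .config import RunConfig, dump_config
from .detect import NoiseModel, detect_minis, estimate_noise, measure_evoked
from .errors import InsufficientDataError, UndefinedEstimateError, ValidationError
from .quantal import (
    classify_failures,
    cumulative_rrp,
    failure_qc,
    fit_parabola,
    qc_ratio,
    vm_params,
    vm_points,
)
from .groupstats import compare_groups, compare_pair
from .simulate import (
    AmplitudeDataset,
    GroundTruth,
    Protocol,
    QuantalKernel,
    render_sweep,
    simulate_cohort,
)

log = logging.getLogger(__name__)

#: inter-stimulus interval used when rendering low-frequency evoked sweeps;
#: far longer than the response decay, so amplitude statistics are
#: unaffected while sweeps stay tractable.
RENDER_ISI_S = 0.5


def _protocols(config: RunConfig) -> list[Protocol]:
    p = config.protocol
    protos = [
        Protocol.spontaneous(duration_s=p.spontaneous_duration_s),
        Protocol.failure(ca_mm=p.failure_ca_mm, n_stim=p.failure_n_stim),
        Protocol.train(ca_mm=p.train_ca_mm, n_stim=p.train_n_stim),
    ]
    levels = list(p.vm_ca_levels)
    if config.analysis.qc_ca_mm not in levels:
        levels.append(config.analysis.qc_ca_mm)
    for ca in sorted(levels):
        protos.append(Protocol.low_freq_evoked(ca_mm=ca, n_stim=p.vm_n_stim))
    return protos


def run_simulate(config: RunConfig, out_dir, force: bool = False) -> Path:
    """Generate amplitude tables (and, in full_trace mode, QTRC sweeps) for
    every genotype under the full protocol battery. Identical config and
    seed reproduce byte-identical tables."""
    out = Path(out_dir)
    if out.exists() and not force:
        # the run log may already live here; anything else blocks the run
        leftovers = [p for p in out.iterdir() if p.name != "run.log"]
        if leftovers:
            raise ValidationError(
                f"output directory {out} is not empty (use force=True / --force)"
            )
    out.mkdir(parents=True, exist_ok=True)
    protos = _protocols(config)
    children = np.random.SeedSequence(config.seed).spawn(len(config.genotypes))
    datasets = []
    for child, (label, truth) in zip(children, config.genotypes.items()):
        log.info("simulating genotype %s (%d NMJs)", label, config.n_nmjs)
        datasets.append(simulate_cohort(truth, protos, config.n_nmjs, child, genotype=label))
    data = AmplitudeDataset.concat(datasets)
    qtrc.write_events(data.events, out / "events.tsv")
    data.nmj_meta.to_csv(out / "nmjs.tsv", sep="\t", index=False, float_format="%.9g")
    data.oracle_counts.to_csv(out / "oracle.tsv", sep="\t", index=False, float_format="%.9g")
    (out / "config.txt").write_text(dump_config(config), encoding="utf-8")
    (out / "run_meta.txt").write_text(
        f"config_hash={config.config_hash()}\nseed={config.seed}\nmode={config.mode}\n",
        encoding="utf-8",
    )
    if config.mode == "full_trace":
        _render_sweeps(config, data, out)
    log.info("simulation written to %s (%d events)", out, len(data.events))
    return out


def _render_sweeps(config: RunConfig, data: AmplitudeDataset, out: Path) -> None:
    """Render spontaneous and quantal-content sweeps to QTRC files."""
    sweep_dir = out / "sweeps"
    sweep_dir.mkdir(exist_ok=True)
    kernel = QuantalKernel()
    rows = []
    rng_root = np.random.SeedSequence(config.seed + 1)
    qc_ca = config.analysis.qc_ca_mm
    nmj_ids = list(data.nmj_meta["nmj_id"])
    for child, nmj_id in zip(rng_root.spawn(len(nmj_ids)), nmj_ids):
        meta_row = data.nmj_meta[data.nmj_meta["nmj_id"] == nmj_id].iloc[0]
        truth = config.genotypes[meta_row["genotype"]]
        ev = data.for_nmj(nmj_id)
        spont = ev[(ev["protocol"] == "spontaneous")]
        rng_a, rng_b = np.random.default_rng(child), np.random.default_rng(child.spawn(1)[0])
        common_meta = dict(
            nmj_id=nmj_id,
            genotype=meta_row["genotype"],
            holding_current_na=float(meta_row["holding_current_na"]),
        )
        sp_sweep = render_sweep(
            kernel,
            config.sample_rate_hz,
            config.protocol.spontaneous_duration_s,
            rng_a,
            mini_times_s=spont["event_time_s"].to_numpy(),
            mini_amplitudes_na=spont["amplitude_na"].to_numpy(),
            noise_sd_na=truth.noise_sd,
            meta=dict(common_meta, protocol="spontaneous", ca_mm=0.5),
        )
        sp_path = sweep_dir / f"{nmj_id}_spont.qtrc"
        qtrc.write_sweep(sp_sweep, sp_path)
        rows.append(dict(path=str(sp_path.relative_to(out)), protocol="spontaneous", ca_mm=0.5, **common_meta))

        evoked = ev[(ev["protocol"] == "low_freq_evoked") & (ev["ca_mm"] == qc_ca)]
        if len(evoked):
            stim_times = 0.2 + RENDER_ISI_S * np.arange(len(evoked))
            duration = stim_times[-1] + RENDER_ISI_S
            ev_sweep = render_sweep(
                kernel,
                config.sample_rate_hz,
                duration,
                rng_b,
                stim_times_s=stim_times,
                evoked_amplitudes_na=evoked["amplitude_na"].to_numpy(),
                noise_sd_na=truth.noise_sd,
                meta=dict(common_meta, protocol="low_freq_evoked", ca_mm=qc_ca),
            )
            ev_path = sweep_dir / f"{nmj_id}_evoked.qtrc"
            qtrc.write_sweep(ev_sweep, ev_path)
            rows.append(
                dict(path=str(ev_path.relative_to(out)), protocol="low_freq_evoked", ca_mm=qc_ca, **common_meta)
            )
    manifest = pd.DataFrame(rows)[
        ["path", "nmj_id", "genotype", "protocol", "ca_mm", "holding_current_na"]
    ]
    qtrc.write_manifest(manifest, out / "manifest.tsv")
    log.info("rendered %d sweeps", len(manifest))


def _config_noise_model(truth: GroundTruth) -> NoiseModel:
    """Amplitude-level noise model: measured amplitudes carry Gaussian error
    of s.d. ``noise_sd`` around zero, so the noise 'distribution' for the
    failure criterion is centered at 0 with that s.d."""
    return NoiseModel(
        mean_na=0.0,
        sd_na=truth.noise_sd,
        sample_sd_na=truth.noise_sd,
        n_windows=8,
        method="analytic",
    )


def run_analyze(config: RunConfig, data_dir, out_dir=None) -> Path:
    """Apply the recording gate, (in full_trace mode) the detection layer,
    and all four quantal estimators; write per-NMJ estimate tables."""
    data_dir = Path(data_dir)
    out = Path(out_dir) if out_dir is not None else data_dir
    out.mkdir(parents=True, exist_ok=True)
    events = qtrc.read_events(data_dir / "events.tsv")
    nmjs = pd.read_csv(data_dir / "nmjs.tsv", sep="\t")

    kept = []
    for _, row in nmjs.iterrows():
        decision = qtrc.recording_qc(row)
        if decision.accepted:
            kept.append(row["nmj_id"])
            if decision.low_holding:
                log.debug("%s: %s", row["nmj_id"], decision.reason)
        else:
            log.info("rejected recording %s: %s", row["nmj_id"], decision.reason)
    nmjs = nmjs[nmjs["nmj_id"].isin(kept)]
    events = events[events["nmj_id"].isin(kept)]

    if config.mode == "full_trace":
        events = _detected_events(config, data_dir, events)

    a = config.analysis
    qc_rows, fail_rows, fit_rows, level_rows, train_rows = [], [], [], [], []
    for _, meta_row in nmjs.iterrows():
        nmj_id = meta_row["nmj_id"]
        genotype = meta_row["genotype"]
        truth = config.genotypes[genotype]
        ev = events[events["nmj_id"] == nmj_id]
        minis = ev[ev["kind"] == "mejc"]["amplitude_na"].to_numpy()
        if minis.size == 0:
            log.warning("%s: no mEJC events; all estimators skipped", nmj_id)
            continue
        mean_mejc = float(minis.mean())

        qc_ev = ev[(ev["protocol"] == "low_freq_evoked") & (ev["ca_mm"] == a.qc_ca_mm)]
        if len(qc_ev):
            s = qc_ratio(
                qc_ev["amplitude_na"].to_numpy(), minis, nmj_id=nmj_id, genotype=genotype, ca_mm=a.qc_ca_mm
            )
            qc_rows.append(vars(s) | {"nmj_id": nmj_id})
        else:
            log.warning("%s: no quantal-content protocol; qc_ratio skipped", nmj_id)

        fail_ev = ev[ev["protocol"] == "failure"]
        if len(fail_ev):
            try:
                cls = classify_failures(
                    fail_ev["amplitude_na"].to_numpy(),
                    _config_noise_model(truth),
                    minis,
                    k_noise=a.k_noise,
                    mini_pct=a.mini_pct,
                )
                res = failure_qc(cls.m_total, cls.n_fail)
                fail_rows.append(
                    dict(
                        nmj_id=nmj_id,
                        genotype=genotype,
                        m_total=res.m_total,
                        n_fail=res.n_fail,
                        qc_fail=res.qc_fail,
                        noise_ceiling_na=cls.noise_ceiling_na,
                        mini_floor_na=cls.mini_floor_na,
                    )
                )
            except (UndefinedEstimateError, InsufficientDataError) as exc:
                log.warning("%s: failure analysis skipped: %s", nmj_id, exc)
        else:
            log.warning("%s: no failure protocol; failure analysis skipped", nmj_id)

        vm_ev = ev[(ev["protocol"] == "low_freq_evoked") & (ev["ca_mm"].isin(config.protocol.vm_ca_levels))]
        if vm_ev["ca_mm"].nunique() >= 3:
            by_ca = {ca: g["amplitude_na"].to_numpy() for ca, g in vm_ev.groupby("ca_mm")}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    series = vm_points(by_ca)
                fit = fit_parabola(series, weights=a.vm_weights)
                params = vm_params(fit, series)
                top = params.iloc[-1]  # highest-calcium level
                fit_rows.append(
                    dict(
                        nmj_id=nmj_id,
                        genotype=genotype,
                        A=fit.A,
                        B=fit.B,
                        n_vm=fit.n_vm,
                        rss=fit.rss,
                        n_constrained=fit.n_constrained,
                        q_na=top["q_na"],
                        p_vr=top["p_vr"],
                        note=fit.note,
                    )
                )
                for _, lr in params.iterrows():
                    level_rows.append(dict(nmj_id=nmj_id, genotype=genotype, **lr.to_dict()))
                if not fit.n_constrained:
                    log.info("%s: %s", nmj_id, fit.note)
            except (InsufficientDataError, ValidationError) as exc:
                log.warning("%s: variance-mean fit skipped: %s", nmj_id, exc)
        else:
            log.warning("%s: <3 calcium levels; variance-mean analysis skipped", nmj_id)

        train_ev = ev[ev["protocol"] == "train"].sort_values("stim_index")
        if len(train_ev):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = cumulative_rrp(train_ev["amplitude_na"].to_numpy(), mean_mejc)
            train_rows.append(
                dict(
                    nmj_id=nmj_id,
                    genotype=genotype,
                    slope_na_per_stim=tr.slope_na_per_stim,
                    intercept_na=tr.intercept_na,
                    n_rrp_train=tr.n_rrp_train,
                    floored=tr.floored,
                )
            )
        else:
            log.warning("%s: no train protocol; cumulative RRP skipped", nmj_id)

    _write(pd.DataFrame(qc_rows), out / "nmj_summary.tsv")
    _write(pd.DataFrame(fail_rows), out / "failure.tsv")
    _write(pd.DataFrame(fit_rows), out / "vm_fit.tsv")
    _write(pd.DataFrame(level_rows), out / "vm_levels.tsv")
    _write(pd.DataFrame(train_rows), out / "train_rrp.tsv")
    log.info("estimates written to %s (%d NMJs analyzed)", out, len(nmjs))
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def _detected_events(config: RunConfig, data_dir: Path, events: pd.DataFrame) -> pd.DataFrame:
    """Replace spontaneous and quantal-content amplitudes with ones
    re-measured from the rendered sweeps through the detection layer."""
    a = config.analysis
    manifest = qtrc.read_manifest(data_dir / "manifest.tsv")
    replaced = []
    drop_mask = pd.Series(False, index=events.index)
    for _, row in manifest.iterrows():
        sweep = qtrc.read_sweep(data_dir / row["path"])
        nmj_id = row["nmj_id"]
        if row["protocol"] == "spontaneous":
            noise = estimate_noise(sweep, method=a.noise_method, robust=True)
            det = detect_minis(sweep, noise, threshold_k=a.threshold_k)
            det2 = det.assign(
                nmj_id=nmj_id,
                genotype=row["genotype"],
                protocol="spontaneous",
                ca_mm=row["ca_mm"],
                stim_index=-1,
                event_time_s=det["time_s"],
            )
            drop_mask |= (events["nmj_id"] == nmj_id) & (events["protocol"] == "spontaneous")
        else:
            noise = estimate_noise(sweep, method=a.noise_method)
            det = measure_evoked(sweep, noise)
            det2 = det.assign(
                nmj_id=nmj_id,
                genotype=row["genotype"],
                protocol="low_freq_evoked",
                ca_mm=row["ca_mm"],
                event_time_s=det["time_s"],
            )
            drop_mask |= (
                (events["nmj_id"] == nmj_id)
                & (events["protocol"] == "low_freq_evoked")
                & (events["ca_mm"] == row["ca_mm"])
            )
        replaced.append(det2[qtrc.EVENT_COLUMNS])
        log.debug("%s %s: %d events from trace", nmj_id, row["protocol"], len(det2))
    out = pd.concat([events[~drop_mask]] + replaced, ignore_index=True)
    return out


#: measures compared across genotypes, with their source table.
MEASURES = {
    "mean_mejc_na": "nmj_summary.tsv",
    "mean_ejc_na": "nmj_summary.tsv",
    "qc": "nmj_summary.tsv",
    "qc_fail": "failure.tsv",
    "n_vm": "vm_fit.tsv",
    "p_vr": "vm_fit.tsv",
    "q_na": "vm_fit.tsv",
    "n_rrp_train": "train_rrp.tsv",
}


def run_compare(config: RunConfig, estimates_dir, out_dir=None) -> pd.DataFrame:
    """Compare genotypes for every measure; write comparisons.tsv and a
    plain-text report (mean +/- s.e.m., significance stars)."""
    est = Path(estimates_dir)
    out = Path(out_dir) if out_dir is not None else est
    out.mkdir(parents=True, exist_ok=True)
    tables = {name: pd.read_csv(est / name, sep="\t") for name in set(MEASURES.values())}
    genotypes = sorted(
        set().union(*(set(t["genotype"].unique()) for t in tables.values() if len(t)))
    )
    if len(genotypes) < 2:
        raise ValidationError("comparison requires >= 2 genotypes")
    rows = []
    report = []
    for measure, table_name in MEASURES.items():
        table = tables[table_name]
        if measure not in table.columns or not len(table):
            continue
        groups = {
            g: table.loc[(table["genotype"] == g) & table[measure].notna(), measure].to_numpy()
            for g in genotypes
        }
        groups = {g: v for g, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            log.warning("measure %s: fewer than 2 groups with n >= 2; skipped", measure)
            continue
        if len(groups) == 2:
            (la, va), (lb, vb) = groups.items()
            res = compare_pair(va, vb, labels=(la, lb))
            rows.append(
                dict(
                    measure=measure,
                    test_used=res.test_used,
                    pair=f"{la} vs {lb}",
                    statistic=res.statistic,
                    p=res.p_value,
                    stars=res.stars,
                )
            )
        else:
            res = compare_groups(groups, alpha_var=config.analysis.alpha_var)
            rows.append(
                dict(
                    measure=measure,
                    test_used=res.test_used,
                    pair="omnibus",
                    statistic=res.statistic,
                    p=res.p_value,
                    stars=res.stars,
                )
            )
            for _, pr in res.pairwise.iterrows():
                rows.append(
                    dict(
                        measure=measure,
                        test_used=res.test_used,
                        pair=f"{pr['A']} vs {pr['B']}",
                        statistic=pr["diff"],
                        p=pr["p"],
                        stars=pr["stars"],
                    )
                )
        report.append(f"{measure} [{res.test_used}]:")
        for s in res.summaries:
            report.append(f"  {s}")
        report.append(f"  p={res.p_value:.4g} {res.stars}")
        report.append("")
    comparisons = pd.DataFrame(rows)
    _write(comparisons, out / "comparisons.tsv")
    (out / "report.txt").write_text("\n".join(report), encoding="utf-8")
    log.info("comparisons written to %s", out)
    return comparisons


def run_all(config: RunConfig, out_dir, force: bool = False) -> pd.DataFrame:
    """simulate -> analyze -> compare in one call."""
    out = run_simulate(config, out_dir, force=force)
    run_analyze(config, out)
    return run_compare(config, out)
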