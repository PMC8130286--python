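"""End-to-end orchestration: synthesize → detect → characterize → network.

The pipeline sequences the analysis stages in the order the method runs:
synthetic-data generation (or recording + candidate-table input), FR
detection, Bayesian parameter estimation, event-locked multiunit
activity, pre/post wavelet coherence, per-event Granger causality and
meta-analytic network construction, plus the conventional nonparametric
group comparisons.  Every stage writes CSV/JSON outputs and a provenance
log (config hash, seeds, versions), so a rerun with the identical config
reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .io import Recording, EventWindow, read_recording, read_event_table, write_event_table
from .synthetic import (
    SynthConfig,
    FREventSpec,
    ThetaCoherenceSchedule,
    VarCoupling,
    SpikeSchedule,
    generate_recording,
)
from .detection import detect_events, FREvent
from .bayes import estimate_parameter, map_point
from .mua import detect_spikes, event_locked_histogram, cumulative_dominance
from .coherence import (
    THETA_BAND,
    GAMMA_BAND,
    event_coherence,
    pre_post_comparison,
)
from .causality import event_causality
from .meta import pool_all_connections, build_network, classify_nodes

log = logging.getLogger("fastripple")

PARAMETERS = ("amplitude_pp", "power_frequency", "duration_ms", "power")


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Either ``synthetic`` (a SynthConfig) or ``recording_path`` (+ optional
    ``candidate_table``) must be given.  Stage toggles enable individual
    analyses; stage parameters have the defaults used throughout the
    package.
    """

    output_dir: str = "fastripple_out"
    synthetic: SynthConfig | None = None
    recording_path: str | None = None
    candidate_table: str | None = None
    event_table: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "detect": True,
            "bayes": True,
            "mua": True,
            "coherence": True,
            "causality": True,
            "network": True,
            "stats": True,
        }
    )
    theta_band: tuple[float, float] = THETA_BAND
    gamma_band: tuple[float, float] = GAMMA_BAND
    mcmc: dict = field(
        default_factory=lambda: {"chains": 4, "draws": 2000, "warmup": 1000}
    )
    causality_subset: str = "sharp_wave_ca1"  # or 'all'
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and self.recording_path is None:
            raise ValueError("config needs either a synthetic block or a recording_path")
        if self.recording_path and not Path(self.recording_path).exists():
            raise ValueError(f"recording_path {self.recording_path} does not exist")
        if self.candidate_table and not Path(self.candidate_table).exists():
            raise ValueError(f"candidate_table {self.candidate_table} does not exist")
        needs_events = any(
            self.stages.get(s)
            for s in ("bayes", "mua", "coherence", "causality", "network", "stats")
        )
        if needs_events and not self.stages.get("detect") and not self.event_table:
            raise ValueError(
                "downstream stages enabled without detection and without an event_table"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synthetic", None)
        if synth is not None:
            events = [FREventSpec(**e) for e in synth.pop("event_specs", [])]
            theta = synth.pop("theta_coherence_schedule", None)
            var = synth.pop("var_coupling", None)
            spikes = synth.pop("spike_schedule", None)
            synth = SynthConfig(
                event_specs=events,
                theta_coherence_schedule=(
                    ThetaCoherenceSchedule(**theta) if theta else ThetaCoherenceSchedule()
                ),
                var_coupling=VarCoupling(**var) if var else VarCoupling(),
                spike_schedule=SpikeSchedule(**spikes) if spikes is not None else None,
                **synth,
            )
        cfg = cls(synthetic=synth, **d)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict_safe(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(obj):
    try:
        return asdict(obj)
    except TypeError:
        return obj.__dict__


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the structured run report.

    A stage failure aborts the run with the stage name and cause; outputs
    written before the failure are retained in ``output_dir``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "version": __version__,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            report["stages"][name] = {"seconds": round(time.time() - t0, 3), **(result or {})}
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return result

        return deco

    # --- input -----------------------------------------------------------
    ground_truth = None
    if cfg.synthetic is not None:
        rec, ground_truth = generate_recording(cfg.synthetic)
        report["stages"]["synth"] = {
            "n_samples": rec.n_samples,
            "n_injected_events": len(ground_truth.events),
        }
    else:
        rec = read_recording(cfg.recording_path)

    # --- detection -------------------------------------------------------
    events: list[FREvent] = []
    if cfg.stages.get("detect", True):
        @stage("detect")
        def _detect():
            candidates = None
            if cfg.candidate_table:
                tab = read_event_table(cfg.candidate_table)
                candidates = {
                    region: [
                        EventWindow(region=region, center_index=int(round(t * rec.fs)))
                        for t in tab[tab.region == region].center_time_s
                    ]
                    for region in rec.region_labels
                }
            for region in rec.region_labels:
                evs, _ = detect_events(
                    rec, region, candidates=candidates[region] if candidates else None
                )
                events.extend(evs)
            for i, ev in enumerate(events):
                ev.event_id = i
            write_event_table(events, out / "events.csv")
            return {"n_events": len(events)}
    elif cfg.event_table:
        tab = read_event_table(cfg.event_table)
        for i, row in tab.iterrows():
            events.append(
                FREvent(
                    region=row["region"],
                    center_time=float(row["center_time_s"]),
                    amplitude_pp=float(row.get("amplitude_pp_uV", np.nan)),
                    power_frequency=float(row.get("power_freq_hz", np.nan)),
                    power=float(row.get("power_uV2_per_hz", np.nan)),
                    duration_ms=float(row.get("duration_ms", np.nan)),
                    mean_frequency=float(row.get("mean_freq_hz", np.nan)),
                    sharp_wave_associated=bool(row.get("sw_flag", 0)),
                    event_id=int(row.get("event_id", i)),
                )
            )

    events_by_region = {
        r: [e for e in events if e.region == r] for r in rec.region_labels
    }

    # --- Bayesian characterization --------------------------------------
    if cfg.stages.get("bayes", True) and events:
        @stage("bayes")
        def _bayes():
            rows = []
            for param in PARAMETERS:
                groups = {
                    r: np.array([getattr(e, param) for e in evs])
                    for r, evs in events_by_region.items()
                    if len(evs) >= 3
                }
                if len(groups) < 1:
                    continue
                draws = estimate_parameter(groups, param, seed=cfg.seed, **cfg.mcmc)
                for region, post in draws.items():
                    mu_map, sigma_map = map_point(post, min_draws=min(1000, len(post.mu)))
                    lo, hi = post.mu_credible_interval()
                    rows.append(
                        {
                            "parameter": param,
                            "region": region,
                            "mu_map": mu_map,
                            "sigma_map": sigma_map,
                            "mu_ci_low": lo,
                            "mu_ci_high": hi,
                            "ess": post.ess,
                            "rhat": post.rhat,
                        }
                    )
                    report["warnings"].extend(
                        {"stage": "bayes", "region": region, "parameter": param, "msg": m}
                        for m in post.warnings
                    )
            pd.DataFrame(rows).to_csv(out / "posterior_summary.csv", index=False)
            return {"n_fits": len(rows)}

    # --- event subset for the event-locked analyses ----------------------
    if cfg.causality_subset == "sharp_wave_ca1":
        locked = [e for e in events if e.region == "CA1" and e.sharp_wave_associated]
        if not locked:  # fall back so small demos still exercise the stages
            locked = [e for e in events if e.region == "CA1"] or events
    else:
        locked = events
    centers = np.array([e.center_time for e in locked])

    # --- multiunit activity ----------------------------------------------
    if cfg.stages.get("mua", True) and len(centers):
        @stage("mua")
        def _mua():
            exclude = [(t - 0.2, t + 0.2) for t in centers]
            span = (rec.start_time, rec.start_time + rec.duration)
            hists = {}
            rows = []
            for region in rec.region_labels:
                train = detect_spikes(rec, region, exclude_windows=exclude)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    h = event_locked_histogram(train, centers, span)
                hists[region] = h
                for k in range(len(h.probability)):
                    rows.append(
                        {
                            "region": region,
                            "bin_start_ms": h.bin_edges_ms[k],
                            "bin_end_ms": h.bin_edges_ms[k + 1],
                            "probability": h.probability[k],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "mua_histograms.csv", index=False)
            dom = {}
            if "CA3" in hists and "CA1" in hists:
                d = cumulative_dominance(hists["CA3"], hists["CA1"])
                dom = {side: {"h1": "CA3", "h2": "CA1", "none": "none", "crossing": "crossing"}[v]
                       for side, v in d.items()}
            return {"dominance_CA3_vs_CA1": dom}

    # --- wavelet coherence ------------------------------------------------
    if cfg.stages.get("coherence", True) and len(centers):
        @stage("coherence")
        def _coh():
            pairs = [("DG", "CA3"), ("DG", "CA1"), ("CA3", "CA1")]
            bands = {"theta": cfg.theta_band, "gamma": cfg.gamma_band}
            rows, tests = [], {}
            for bname, band in bands.items():
                for pair in pairs:
                    if not all(p in rec.region_labels for p in pair):
                        continue
                    results, kept = [], []
                    for e, t0 in zip(locked, centers):
                        try:
                            results.append(event_coherence(rec, pair, t0, band))
                            kept.append(e)
                        except ValueError:
                            continue
                    for e, r in zip(kept, results):
                        rows.append(
                            {
                                "event_id": e.event_id,
                                "pair": "-".join(pair),
                                "band": bname,
                                "mean_pre": r.mean_pre,
                                "mean_post": r.mean_post,
                            }
                        )
                    tests[f"{bname}:{'-'.join(pair)}"] = pre_post_comparison(results)
            pd.DataFrame(rows).to_csv(out / "coherence_summary.csv", index=False)
            (out / "coherence_tests.json").write_text(json.dumps(tests, indent=1))
            return {"tests": tests}

    # --- Granger causality -----------------------------------------------
    epoch_results = []
    if cfg.stages.get("causality", True) and len(centers):
        @stage("causality")
        def _causality():
            rows = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for e, t0 in zip(locked, centers):
                    res = event_causality(rec, t0, event_id=e.event_id or 0, duration_ms=e.duration_ms if np.isfinite(e.duration_ms) else 0.0)
                    if res is None:
                        continue
                    epoch_results.append(res)
                    for epoch, mat, ok in (
                        ("pre", res.pre_matrix, res.pre_stationary),
                        ("post", res.post_matrix, res.post_stationary),
                    ):
                        for i, ci_ in enumerate(res.regions):
                            for j, cj in enumerate(res.regions):
                                if i == j:
                                    continue
                                rows.append(
                                    {
                                        "event_id": res.event_id,
                                        "epoch": epoch,
                                        "cause": ci_,
                                        "effect": cj,
                                        "p_value": mat[i, j],
                                        "stationarity_pass": ok,
                                    }
                                )
            pd.DataFrame(rows).to_csv(out / "causality_epochs.csv", index=False)
            n_usable = sum(r.usable for r in epoch_results)
            return {"n_events": len(epoch_results), "n_usable": n_usable}

    # --- meta-analytic network -------------------------------------------
    if cfg.stages.get("network", True) and epoch_results:
        @stage("network")
        def _network():
            pooled = pool_all_connections(epoch_results)
            rows = []
            nets = {}
            for epoch in ("pre", "post"):
                for c in pooled[epoch]:
                    rows.append(
                        {
                            "epoch": epoch,
                            "cause": c.cause,
                            "effect": c.effect,
                            "n": c.n,
                            "count_significant": c.count_significant,
                            "count_significant_raw": c.count_significant_raw,
                            "mean_p": c.mean_p,
                            "Z": c.z,
                            "overall_p": c.overall_p,
                            "retained": c.retained,
                        }
                    )
                net = build_network(pooled[epoch], epoch, epoch_results[0].regions)
                nets[epoch] = {
                    "edges": sorted(net.edge_set()),
                    "unit_causal_density": net.unit_causal_density,
                    "causal_flow": net.causal_flow,
                    "roles": classify_nodes(net),
                }
            pd.DataFrame(rows).to_csv(out / "network_report.csv", index=False)
            (out / "causal_network.json").write_text(json.dumps(nets, indent=1))
            return {"networks": nets}

    # --- conventional statistics -----------------------------------------
    if cfg.stages.get("stats", True) and events:
        @stage("stats")
        def _stats():
            table = compare_parameters(events_by_region)
            (out / "group_comparisons.json").write_text(json.dumps(table, indent=1))
            return {"comparisons": table}

    (out / "provenance.json").write_text(json.dumps(report["provenance"], indent=1))
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def compare_parameters(
    events_by_region: dict[str, list], min_n: int = 3, holm: bool = False
) -> dict:
    """Nonparametric group comparison of FR parameters across regions.

    Per parameter: a Lilliefors normality screen per region (the Q–Q
    heuristic made quantitative), a Kruskal–Wallis omnibus test, and
    pairwise rank-sum tests (unadjusted by default; optional Holm
    adjustment).
    """
    from statsmodels.stats.diagnostic import lilliefors
    from statsmodels.stats.multitest import multipletests

    out: dict = {}
    for param in PARAMETERS:
        groups = {
            r: np.array([getattr(e, param) for e in evs])
            for r, evs in events_by_region.items()
            if len(evs) >= min_n
        }
        if len(groups) < 2:
            out[param] = {"status": "insufficient n"}
            continue
        entry: dict = {"status": "ok", "normality": {}, "pairwise": {}}
        for r, vals in groups.items():
            if len(vals) >= 4 and np.std(vals) > 0:
                _, p_lf = lilliefors(vals, dist="norm")
                entry["normality"][r] = {"lilliefors_p": float(p_lf)}
        kw = stats.kruskal(*groups.values())
        entry["kruskal_wallis_p"] = float(kw.pvalue)
        labels = list(groups)
        raw = []
        pairs = []
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                p = float(stats.ranksums(groups[labels[a]], groups[labels[b]]).pvalue)
                raw.append(p)
                pairs.append(f"{labels[a]}-{labels[b]}")
        if holm and raw:
            raw = list(multipletests(raw, method="holm")[1])
        for name, p in zip(pairs, raw):
            entry["pairwise"][name] = {"p": p, "tier": _tier(p)}
        out[param] = entry
    return out


def _tier(p: float) -> str:
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


def trisynaptic_coupling(
    epoch: str,
    weight: float = 0.32,
    self_weight: float = 0.2,
    lag_samples: int = 15,
) -> np.ndarray:
    """Adjacency stack planting the trisynaptic pre/post edge sets.

    Region order (DG, CA3, CA1); entry [k, i, j] couples channel j's past
    at lag k+1 into channel i.  Cross-region coupling acts at
    ``lag_samples`` (3 ms at 5 kHz, a realistic synaptic delay); each
    channel keeps a lag-1 self term.  The pre-event network closes the
    loop through the CA3→DG back-projection {DG→CA3, CA3→DG, CA3→CA1,
    CA1→CA3}; the post-event network is the canonical feed-forward
    circuit with the CA1→CA3 return {DG→CA3, CA3→CA1, CA1→CA3}.
    """
    g = weight
    if epoch == "pre":
        C = np.array([[0.0, g, 0.0], [g, 0.0, g], [0.0, g, 0.0]])
    elif epoch == "post":
        # the lone feed-forward DG drive needs more weight than the loop
        # members to be comparably detectable; CA3->CA1 likewise competes
        # with the CA1->CA3 return
        C = np.array([[0.0, 0.0, 0.0], [1.6 * g, 0.0, g], [0.0, 1.2 * g, 0.0]])
    else:
        raise ValueError(f"epoch must be 'pre' or 'post', got {epoch!r}")
    A = np.zeros((lag_samples, 3, 3))
    A[0] = self_weight * np.eye(3)
    A[lag_samples - 1] += C
    return A


def cohort_config(
    n_events: int = 40,
    seed: int = 0,
    spacing_s: float = 1.6,
    coupling_weight: float = 0.32,
    with_spikes: bool = False,
) -> SynthConfig:
    """Synthetic cohort of sharp-wave-associated CA1 fast ripples.

    Events are evenly spaced; the directed coupling switches from the
    pre-event loop to the post-event feed-forward circuit around each
    event center, and theta coherence rises in the 200 ms before each
    event.  This is the standard test bed for the event-locked stages.
    """
    rng = np.random.default_rng(seed)
    events = [
        FREventSpec(
            region="CA1",
            t_center=1.0 + k * spacing_s,
            duration_ms=float(rng.uniform(150, 250)),
            carrier_freq=float(rng.uniform(280, 420)),
            amplitude_pp=float(rng.uniform(35, 65)),
            sharp_wave=True,
            sharp_wave_duration_ms=float(rng.uniform(100, 240)),
        )
        for k in range(n_events)
    ]
    return SynthConfig(
        duration_s=1.0 + n_events * spacing_s + 1.0,
        event_specs=events,
        var_coupling=VarCoupling(
            pre=trisynaptic_coupling("pre", coupling_weight),
            post=trisynaptic_coupling("post", coupling_weight),
        ),
        spike_schedule=SpikeSchedule() if with_spikes else None,
        seed=seed,
    )


def default_demo_config(seed: int = 0, output_dir: str = "fastripple_out") -> PipelineConfig:
    """Small synthetic cohort exercising every stage in about a minute."""
    rng = np.random.default_rng(seed)
    events = []
    t = 2.0
    for k in range(10):
        region = ("CA1", "CA3", "DG")[k % 3] if k >= 6 else "CA1"
        events.append(
            FREventSpec(
                region=region,
                t_center=t,
                duration_ms=float(rng.uniform(150, 250)),
                carrier_freq=float(rng.uniform(280, 420)),
                amplitude_pp=float(rng.uniform(40, 80)),
                sharp_wave=region == "CA1",
            )
        )
        t += 1.8
    pre = trisynaptic_coupling("pre")
    post = trisynaptic_coupling("post")
    synth = SynthConfig(
        duration_s=t + 1.0,
        event_specs=events,
        var_coupling=VarCoupling(pre=pre, post=post),
        spike_schedule=SpikeSchedule(),
        seed=seed,
    )
    return PipelineConfig(
        synthetic=synth,
        output_dir=output_dir,
        mcmc={"chains": 2, "draws": 500, "warmup": 300},
        seed=seed,
    )
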