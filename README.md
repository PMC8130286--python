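# fastripple

Analysis of hippocampal **fast ripples** — pathological 250–600 Hz local
field potential (LFP) oscillations that mark epileptogenic tissue — in
multichannel intracranial recordings from the trisynaptic circuit
(dentate gyrus DG → CA3 → CA1), together with a synthetic-data generator
that provides known ground truth for every stage.

The package is aimed at electrophysiologists and methods developers who
want a tested, reproducible implementation of the full fast-ripple
workflow on 3-channel rodent hippocampal LFP sampled at 5 kHz:

1. **Detection** — candidate windows (automatic envelope proposer or an
   external candidate table) are screened against mains contamination
   (60-Hz component > 15 µV) and movement artifacts (raw peak-to-peak
   > 150 µV), confirmed by a Morlet continuous wavelet transform bound to
   250–600 Hz, and parametrized on the zero-phase band-filtered segment:
   peak-to-peak amplitude, power frequency (highest PSD peak), power
   (PSD at the power frequency, µV²/Hz), duration, and PSD-weighted mean
   frequency, plus sharp-wave association (> 70 ms slow deflection).
2. **Bayesian characterization** — for each parameter x and region, a
   robust Student-t model in the BEST family:
   x ~ T(ν, µ, σ) with µ ~ N(x̄, 2s), σ ~ U(min, max) over the
   parameter's physical range, ν ~ Exponential(mean 30); MCMC posterior
   with MAP of the joint (µ, σ) density.
3. **Multiunit activity (MUA)** — spikes from the > 300 Hz trace at a
   two-z-score threshold; event-locked 20-ms-bin probability histograms
   (probability = count / (n_obs × bin width)) and first-order dominance
   of cumulative spike distributions.
4. **Wavelet coherence** — theta (4–7 Hz) and gamma (30–90 Hz)
   coherence around events, paired pre/post comparison (Wilcoxon).
5. **Granger causality** — bivariate autoregressive F-tests (BIC model
   order, covariance-stationarity screen) on 200-ms windows before and
   after each event, giving a 3×3 directed p-value matrix per event.
6. **Meta-analytic network** — per-event Bonferroni adjustment, pooling
   per directed connection with the normal-curve method

       Z = (x̄ − 0.5) / (0.2887 / √n),   overall p = Φ(Z),

   and graph metrics on the significant edges: unit causal density
   (significant interactions at a node / number of nodes; maxima are
   causal hubs) and causal flow (out-degree − in-degree; sources > 0,
   sinks < 0, and Σ flow = 0 exactly).

## Worked example

```python
import fastripple as fr

# a 40-event cohort of sharp-wave-associated CA1 fast ripples with a
# pre-event coupling loop {DG<->CA3, CA3<->CA1} and a post-event
# feed-forward circuit {DG->CA3, CA3->CA1, CA1->CA3}
cfg = fr.cohort_config(n_events=40, seed=0)
rec, truth = fr.generate_recording(cfg)

events, report = fr.detect_events(rec, "CA1")
print(len(events), "events;", sum(e.sharp_wave_associated for e in events),
      "sharp-wave associated")

results = [
    fr.event_causality(rec, e.center_time, event_id=i, duration_ms=e.duration_ms)
    for i, e in enumerate(events)
]
pooled = fr.pool_all_connections([r for r in results if r is not None])
net_pre = fr.build_network(pooled["pre"], "pre", rec.region_labels)
net_post = fr.build_network(pooled["post"], "post", rec.region_labels)
print("pre edges: ", sorted(net_pre.edge_set()))
print("post edges:", sorted(net_post.edge_set()))
print("post flow:  ", net_post.causal_flow)
```

prints

```
39 events; 39 sharp-wave associated
pre edges:  [('CA1', 'CA3'), ('CA3', 'CA1'), ('CA3', 'DG'), ('DG', 'CA3')]
post edges: [('CA1', 'CA3'), ('CA3', 'CA1'), ('DG', 'CA3')]
post flow:   {'DG': 1, 'CA3': -1, 'CA1': 0}
```

i.e. the detector recovers the injected events, the pooled pre-event
network is the closed loop through the CA3→DG back-projection with zero
net causal flow, and the post-event network is the canonical
feed-forward circuit with DG as the causal source and CA3 as the sink.

A complete run of every stage (detection → Bayesian fits → MUA →
coherence → causality → network → group statistics), with all CSV/JSON
outputs and a provenance log, is one call:

```bash
fastripple all --seed 1 --output-dir out/
```

## Layout

| module | contents |
| --- | --- |
| `fastripple.io` | Recording/EventWindow containers, CSV + EDF I/O, zero-phase FIR filters |
| `fastripple.synthetic` | multichannel LFP generator with ground truth (events, coupling, spikes) |
| `fastripple.detection` | candidate proposal, screen, CWT confirmation, parameters, sharp waves |
| `fastripple.bayes` | BEST-style t-model, MCMC posteriors, MAP, spectral composition |
| `fastripple.mua` | spike extraction, event-locked histograms, cumulative dominance |
| `fastripple.coherence` | Morlet CWT, smoothed wavelet coherence, pre/post tests |
| `fastripple.causality` | stationarity screen, BIC lag selection, Granger F-tests |
| `fastripple.meta` | Bonferroni, normal-curve pooling, causal networks, node roles |
| `fastripple.pipeline` | orchestration, group statistics, cohort/demo configs |
| `fastripple.cli` | `fastripple` command-line entry point |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
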