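# fhrtrend

Analysis of continuously monitored intrapartum fetal heart rate (FHR):
how does the fetal heart rate develop in the final hours of labour, and
does that development differ between neonates with normal and adverse
outcomes?

The package is aimed at perinatal researchers and biomedical signal-
processing engineers working with continuous Doppler FHR recordings
(2 Hz heart-rate logs with heavy dropout, e.g. from portable monitors
used in low-resource settings). It provides, as a tested library plus a
set of analysis drivers:

1. **Noise removal (`fhrtrend.cleaning`).** Doppler FHR contains short
   artefact segments far outside physiology. Gaps are filled by
   forward/backward replication only to let a change detector run; a
   segment is removed when it is bounded by tick-to-tick jumps larger
   than a threshold (default 25 bpm per 0.5 s tick) and returns to its
   pre-jump level in under 30 s. Longer excursions are *kept* — with no
   beat-level ground truth, only "temporary and physiologically
   impossible" is safe to call noise. All analyses use measured samples
   only; no imputation.
2. **Maternal/fetal ambiguity (`fhrtrend.ambiguity`).** At time points
   where both FHR and the intermittent maternal heart rate (MHR) are
   measured, the pair h_t = [fhr(n_t), mhr(m_t)] is *ambiguous* when
   |fhr − mhr| ≤ T_mhr (default 5 bpm). The ambiguity rate is
   mhr_amb = (1/N_H) Σ_{h_t ∈ H} I(h_t) over the pooled pair set H.
3. **Windowed median trend (`fhrtrend.trend`).** For each non-overlapping
   window of Δ seconds (index p = (t + t0)/Δ over the last t0 = 9000 s
   before birth), the trend mFHR(p) is the *median of all measured
   samples pooled across a group's episodes*, with the 1st/3rd quartiles
   HRq1/HRq3 as spread. The pre-birth shift is tested with the Wilcoxon
   signed-rank test on per-episode window medians; groups are compared
   with Kruskal–Wallis on the same per-episode medians.
4. **Windowed densities (`fhrtrend.distribution`).** Per window, episode
   histograms over integer bins l = 50…200 bpm are summed and normalized
   (h̄(l) = h(l)/N); σ²_PDF is the variance of the implied heart-rate
   distribution; stacked windows give the pdf-over-time surface with the
   per-window episode-support count.
5. **Synthetic cohort (`fhrtrend.simulate`).** The clinical recordings
   this framework was designed around are access-restricted, so a seeded
   generator emulates them — group-specific baseline profiles with a
   pre-birth drop, AR(1) within-episode variability that grows toward
   birth, ~30% dropout, ~1.8% removable spike noise, intermittent MHR
   (~0.4% coverage in ~30% of episodes) with injected maternal pickup,
   and optional clock drift — with full per-episode ground truth for
   testing every stage.

Time is referenced to birth (t = 0, negative before birth); episodes
whose clock drifted past birth are corrected by shifting the time of
birth to the last measured FHR sample.

## Worked example

Run the numbered drivers over the default synthetic study conditions
(230 episodes: 200 normal, 20 NCU, 6 VEND, 4 FSB):

```
python analysis/01_simulate_cohort.py --seed 1 --out results
python analysis/02_clean_cohort.py    --seed 1 --out results
python analysis/03_ambiguity.py       --seed 1 --out results
python analysis/04_trend.py           --seed 1 --out results
python analysis/05_distribution.py    --seed 1 --out results
```

which prints (seed 1):

```
injected spike ticks removed: 134100/134403 (99.8%)
per-episode removed data: 1.88 ± 0.10 %
per-episode missing data: 30.08 ± 14.91 %
pooled MHR/FHR ambiguity at T_mhr = 5 bpm: 4.22%
pooled mFHR (all labeled, 10-min windows): 134.7 bpm at 150-140 min -> 119.0 bpm in the last 10 min
  shift test (all, n=186 paired episodes): p = 2.84e-32
normal: 90-60 min: peak 138 bpm, sigma2 152, 60-30 min: peak 135 bpm, sigma2 175, 30-0 min: peak 129 bpm, sigma2 225
perinatal: 90-60 min: peak 131 bpm, sigma2 165, 60-30 min: peak 132 bpm, sigma2 206, 30-0 min: peak 105 bpm, sigma2 308
```

Reading these numbers: cleaning removes ≈1.9% of measured samples and
recovers 99.8% of the noise the generator injected; ≈4% of jointly
measured time points are maternal/fetal-ambiguous at 5 bpm; the pooled
median FHR falls ≈15 bpm over the last 150 min (a shift that is highly
significant on per-episode medians); and the heart-rate distribution
widens toward birth in every group, with the perinatal-mortality peak
dropping to ≈105 bpm in the final half hour while the normal group's peak
stays near 130–140 bpm.

The same stages are available as a CLI over on-disk cohorts
(`fhr-pipeline simulate/clean/ambiguity/trend/pdf/report/run-all`); the
CSV layout is documented in `fhrtrend.episode`.

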