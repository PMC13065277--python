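# triadtalk

Conversational-behavior analytics for triadic (three-person) hearing
experiments in audiovisual virtual reality and telepresence.

Hearing researchers increasingly evaluate hearing devices during free,
interactive conversation rather than with isolated listening tests.  In
such experiments, each interlocutor's microphone yields a short-term
sound-level trace, a motion-capture system records the participant's
head pose, and a questionnaire captures the subjective experience after
each condition of a 2 (background noise: quiet vs. noise) x 4 (avatar
head-movement animation: static, automatic, transmitted, video)
repeated-measures design.  `triadtalk` turns those streams into the
standard behavioral measures and their factorial statistics:

* **Speech activity** — levels are smoothed (first-order 10 Hz
  Butterworth on linear power, then a rolling 100 ms Hann window on dB),
  a noise floor is fitted to the sorted level distribution, and the
  activity threshold sits at the 25% point of the dynamic range above
  the floor.  Supra-threshold runs separated by pauses < 1.25 s merge
  into *utterances*; merged segments < 0.05 s are discarded.
* **Voice measures** — speech level (95th percentile of levels during
  activity), median utterance duration, and the Lombard slope
  `10 * (L_noise - L_quiet) / delta_noise` in dB per 10 dB of noise.
* **Turn taking** — floor transfers between different speakers with
  signed floor-transfer offsets (FTO): gaps > 0, overlaps < 0; failed
  interjections (backchannels) and same-speaker resumptions are not
  transfers.  Medians, rates per minute and 250 ms FTO histograms.
* **Head movement** — angular distance of head yaw to the single active
  confederate's face (optionally referenced to the individual per-avatar
  median), the P95 - P5 yaw range split by listening/speaking (speaking
  periods < 15 s are excluded), and the median head translation toward
  the screen (lean-in).
* **Ratings** — 10 items on a 7-point scale (-3..+3, 0.5 steps); Q10 is
  reverse-scored; one-factor models (ML or principal-axis, regression
  factor scores) summarise "sense of presence" (Q1-Q5, Q7) and
  "perceived conversation success" (Q6, Q8-Q10).
* **Statistics** — 2x4 repeated-measures ANOVA with Mauchly's test,
  Greenhouse-Geisser correction, partial eta-squared and Bonferroni
  pairwise comparisons; Kruskal-Wallis with Dunn's post-hoc for ratings.

Because recordings of real sessions are typically not shareable, the
package ships a **synthetic session generator** with known ground truth:
a semi-Markov floor-holder chain over three speakers, Lombard-scaled
level traces over condition-dependent noise floors, head yaw tracking
the active speaker with lag and undershoot, noise-dependent lean-in, and
latent-factor-driven ratings.  Every stage of the pipeline can therefore
be validated by parameter recovery.

## Worked example

```python
import numpy as np
import triadtalk as tt
from triadtalk import pipeline

cfg = tt.GeneratorConfig(duration_s=120.0)          # 2 min per condition
bundles = [tt.generate_session(cfg, f"P{i+1:02d}",
                               np.random.SeedSequence([42, i]))
           for i in range(4)]
table, ratings = pipeline.study_measures([b.session for b in bundles])

slopes = pipeline.lombard_slopes(table)
print("Lombard slope (dB per 10 dB):",
      round(slopes["slope_db_per_10db"].mean(), 2))

events = pipeline.study_turn_events([b.session for b in bundles])
gaps = [e.offset_s for c, evs in events.items() if c.noise == "quiet"
        for e in evs if e.kind == "gap"]
print("median speech gap in quiet (s):", round(np.median(gaps), 3))

ht = table.slice("head_translation").pivot_table(
    index="participant", columns="noise", values="value")
print("lean-in toward the screen in noise (cm):",
      round((ht["noise"] - ht["quiet"]).mean() * 100, 1))

report = pipeline.behavioral_statistics(table, measures=["speech_level"])
ne = report["speech_level"]["noise"]
print(f"speech level ~ noise: F(1,{int(ne.df2)}) = {ne.statistic:.1f}, "
      f"p = {ne.p:.2g}, partial eta^2 = {ne.eta_p2:.3f}")
```

Output:

```
Lombard slope (dB per 10 dB): 4.8
median speech gap in quiet (s): 0.502
lean-in toward the screen in noise (cm): 3.0
speech level ~ noise: F(1,3) = 3875.4, p = 9.1e-06, partial eta^2 = 0.999
```

The generator raised speech levels by 4.6 dB per 10 dB of extra noise;
the analysis recovers 4.8 (the slight excess is the noise floor's power
contribution to measured levels).  Gaps at floor transfers were drawn
with a 0.50 s median, the head moved 3 cm toward the screen in noise,
and the ANOVA flags the Lombard effect with a near-unit effect size.

## Command line

```bash
triadtalk simulate --seed 1 --out-dir study/       # synthetic cohort
triadtalk detect --trace levels.csv --speaker participant --out-dir out/
triadtalk turns --segments segments.tsv --duration 300 --out-dir out/
triadtalk measures --study-dir study/ --out measures.tsv
triadtalk report --study-dir study/ --out-dir report/
```

`report` writes the measure table (TSV), pooled ratings (CSV),
per-participant Lombard slopes and a JSON statistics report (ANOVA and
Kruskal-Wallis tables).

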