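# flocknet

Social network inference from RFID feeder logs, end to end: from a raw
stream of PIT-tag (passive integrated transponder) reads to
permutation-tested conclusions about where individuals sit in their
social network.

The package is aimed at behavioural ecologists running captive or
field studies in which tagged animals visit antenna-equipped feeders. It
implements the standard analysis chain for such data:

1. **Gathering-event detection** — feeder visits arrive in bursts while a
   foraging flock occupies the feeder. A one-dimensional temporal
   Gaussian mixture model (EM, BIC model selection, post-hoc merging of
   overlapping components) clusters reads into events without any
   hand-picked time window.
2. **Association networks** — edges are the simple ratio index,
   `w_ij = x / (x + y_i + y_j)`: the probability of observing two
   individuals in the same rather than different foraging groups. One
   network spans the study; daily networks support repeated-measures
   models.
3. **Assortment** — weighted categorical assortment coefficients `r`
   (family, mated pair) with delete-one-edge jackknife standard errors
   and within-room node-label permutation p-values.
4. **Node metrics** — unweighted degree, strength, betweenness (raw
   shortest-path counts, weighted via the 1/w distance), eigenvector
   centrality, social differentiation (CV of a bird's edge weights), mean
   association with own parents, and ICC repeatability across days.
5. **Permutation-tested mixed models** — daily metrics of treated vs
   control chicks are modelled with a linear mixed model (treatment, day,
   sex, treatment×day, treatment×sex; random intercepts individual ⊂
   family ⊂ room) and coefficient significance comes from constrained
   data-stream permutations: checkerboard swaps of birds between events
   within (day, room) strata, which preserve event sizes and each bird's
   sampling effort.

Because real PIT-tag datasets of this design are rarely shareable, the
package ships a first-class synthetic generator (`flocknet.simulate`)
that emulates the design it analyses — families of parents and chicks in
two rooms, within-brood assignment of a corticosterone (CORT) treatment,
bursty feeder visits biased toward kin and mates, treatment effects on
gregariousness and parental association — with ground-truth events
retained, so the entire chain is verifiable without external data.

## Worked example

```
flocknet run-all --out demo/ --seed 4 --perms 200 --estimator ols
```

prints

```
birds: 63  reads: 67694
events: 2621 detected / 2683 true
family assortment r = 0.149 +/- 0.020 (p = 0.0010)
pair assortment   r = 0.034 +/- 0.015 (p = 0.0010)
treatment effect on degree: 0.391 (p = 0.0647, 200 permutations)
```

Reading this: the simulated study produced 67 694 reads from 63 birds
over 35 days; event detection recovered 2621 foraging events against
2683 ground-truth events (~98%). Edge weights concentrate within
families (r = 0.149) and within mated pairs beyond the family effect
(r = 0.034), both far outside their label-permutation nulls (p = 0.001
is the floor at 1000 draws). CORT chicks foraged with more distinct
flock-mates per day than their control siblings (positive degree
coefficient); the stream-permutation p is moderate because the null
itself preserves how often each bird forages, so only the
composition-driven part of the effect is tested — see
`docs/methods.md`.

Every stage is also available separately (`flocknet simulate`,
`detect-events`, `networks`, `metrics`, `assort`, `permtest`), reading
and writing plain CSV so real logger exports with
`timestamp,tag,feeder_id` columns drop straight in, and as library
functions (`flocknet.detect_events`, `flocknet.sri`, …).

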