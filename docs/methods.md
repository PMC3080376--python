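# Methods

## The model

`hepapop` simulates how the inflammatory cytokine TNFα decides between
survival and apoptosis in primary hepatocytes. TNFα alone does not kill these
cells; it kills when transcription is blocked (actinomycin D, ActD), when
translation is blocked (cycloheximide, CHX), or when it is followed by a Fas
ligand (FasL) stimulus after a sensitizing preincubation. The model is a
deterministic mass-action ODE system with 53 species and 74 rate parameters,
in three coupled blocks:

1. **Receptor core (37 species).** TNFα converts a constitutively turned-over
   receptor pool (`complex0`) into the membrane complex `complex1`, which (i)
   activates the MKK7→JNK kinase cascade and (ii) matures, by FADD
   recruitment, into the cytosolic death complex `complex2` where caspase-8
   is weakly activated. FasL assembles the DISC from a `proDISC` pool and the
   shared FADD pool; caspase-8 activation there is ten-fold stronger.
   Both death complexes are competitively sequestered by cFLIP. Active
   caspase-8 cleaves Bid to tBid; phospho-JNK phosphorylates Bim to pBim;
   Bcl2 stoichiometrically neutralizes both BH3-only products; free pBim/tBid
   catalytically activate Bax/Bak. JNK signalling is shaped by a
   self-terminating loop: pJNK activates a phosphatase that switches MKK7
   off, and MAP-kinase phosphatases (MKPs) continuously dephosphorylate
   pJNK. Under CHX (and only then), pJNK triply phosphorylates the ubiquitin
   ligase Itch, whose active form degrades cFLIP.

2. **NF-κB module (16 species).** The published two-compartment
   IKK/IκBα/A20/NF-κB regulatory module, adopted with three changes: the
   cytoplasm:nucleus volume ratio is 3 (hepatocytes rather than fibroblasts),
   time is rescaled from seconds to hours (all rates × 3600), and its generic
   NF-κB target gene is repurposed as the transcript of a ROS-scavenger
   protein P. Every transcript-synthesis term carries a (1−ActD) gate;
   the translation of P carries a (1−CHX) gate. P_mRNA induction reads the
   nuclear NF-κB *excess over its resting level*, so the unstimulated model
   is an exact fixed point and only TNF-induced P is tracked — the module's
   resting state has a small but nonzero free nuclear NF-κB, and without the
   baseline subtraction P would accumulate without bound at rest.

3. **Discrete mechanisms.** Mitochondrial ROS release is a prescribed
   rectangular pulse: 100 AU released over 0.1 h centred at t = 4 h whenever
   TNFα has been on since t = 0 and the antioxidant BHA is absent.
   Mitochondrial outer-membrane permeabilisation (MOMP) is a latched event:
   when the activated Bax/Bak fraction first reaches 20%, the entire
   mitochondrial cytochrome-c pool moves to the cytosol instantaneously and
   the event can never re-fire. Cytosolic cytochrome c and caspase-8 activate
   caspase-3 from a finite pro-caspase pool; XIAP stoichiometrically absorbs
   active caspase-3.

The fate logic that emerges: under TNFα alone the 4-h ROS burst is destroyed
within minutes by NF-κB-induced P, so JNK shows only its early transient peak
and the Bcl2 buffer survives — no caspase-3. Under TNF+ActD (or +CHX) P is
never made, ROS oxidize the MKPs and linearly drive JNK synthesis
(+k_jnk_inc·ROS), pJNK rises into a sustained second phase, pBim exhausts the
Bcl2 buffer, the trickle of complex2-derived tBid tips Bax/Bak past the MOMP
threshold, and caspase-3 reaches the pool-limited maximum. FasL alone
activates caspase-8 strongly but tBid stays buffered; the direct
caspase-8→caspase-3 route gives the intermediate, XIAP-limited ("type I")
response. Sensitizing works because the TNF phase silently consumes part of
the Bcl2 buffer, so the later FasL-driven tBid wave breaks through.

## Units, initial state, inputs

Core species are dimensionless "percent" amounts (AU): signalling pools
(complex0, proDISC, cFLIP, JNK, proMKK7, Itch, prophosphatase) start at 100,
MKP at 50, FADD at 200 (a common pool for complex2 and DISC assembly), ROS at
0, every activated or complexed form at 0. The mitochondrial-arm pools (Bim,
Bcl2, Bid, BaxBak, Cytc_mito, proC8, proC3) start at 100 with Bim = Bcl2
exactly — phospho-Bim alone can at most exhaust the buffer, never overshoot
it, which is what makes the Bid knockout protective. XIAP starts at 80, large
relative to the caspase-3 pool (100): the none/medium/high contrast between
scenarios lives in the conversion fraction above this absorption threshold.
NF-κB-module species are in the source model's micromolar units; its resting
state is computed once by long unstimulated integration (residual < 1e-8)
and cached. Stimuli are Boolean 0/1 inputs; ActD/CHX/BHA act from t = 0
(experimentally they are added 30 min before TNFα, i.e. before model time
zero), FasL is a sustained step at a protocol-defined onset time.

## Parameters

Of the 74 rate constants, the following are fixed by the study's own printed
values: k_asm_c1 = 0.05, k_asm_c2 = 0.001, k_c8_disc = 0.8,
k_c8_c2 = 0.08 (ten-fold weaker at complex2), k_flip_disc = k_flip_c2 = 8,
k_phos_jnk = 0.4, k_deph_jnk = 0.9, k_jnk_inc = 2, k_ox_mkp = 0.1,
k_rec_mkp = 0.01, k_scav = 1, k_transl_P = 25; the Itch chain rates are
increasing (0.002 < 0.02 < 0.2, cooperativity); the MOMP threshold is 20%
and the ROS pulse carries 100 AU at 4 h. The 30 NF-κB-module constants are
the source module's values converted to hours
(`src/hepapop/data/nfkb_parameters.json`), except the two P-gene constants
(c1p = 30 /h per µM excess nuclear NF-κB, c3p = 0.5 /h), which were fitted so
that P accumulated by 4 h (~200 AU) neutralizes the 100-AU ROS pulse within
minutes — the behaviour the TNF-alone scenario requires.

All remaining constants were calibrated by iterative manual refinement
against the qualitative requirement profile (the seven-constraint checker in
`analysis_tools.check_constraints`, the pJNK peak/termination/second-phase
shape, the ROS plateau, the 507-AU total-JNK readout, and the
robust/fragile verdicts) and then frozen in `model_core.py`. Choices a
maintainer should know about:

- **JNK loop** (k_act_mkk7 = 0.6, k_deph_mkk7 = 75, k_act_ppase = 2.7e-3,
  k_dec_ppase = 2e-5, k_dec_c1 = 1.0): the phosphatase behaves as a slow
  integrator of pJNK exposure; MKK7 retains a small residual activity at
  late times, which is exactly what lets the ROS-driven second phase start
  from a standing cascade.
- **Complex2 flux saturation** (k_dec_c1 = 1.0 vs k_asm_c2·FADD = 0.2):
  at default, ~17% of complex1 matures to complex2; scaling k_asm_c2 a
  hundred-fold up saturates that share near 100% (≤ 6× more flux) and a
  hundred-fold down still leaves a workable trickle. Together with the
  free-complex2 decay (k_dec_c2 = 1, negligible at default, dominant when
  complex2 is overproduced) this is what makes the survival/apoptosis
  pattern robust to four orders of magnitude in k_asm_c2.
- **Bcl2 arithmetic**: under TNFα the early JNK peak converts ~45% of Bim
  and caspase-8 cleaves ~15% of Bid, consuming about half of the Bcl2
  buffer — enough margin for survival, little enough that the FasL wave in
  the sensitizing protocol breaks through. Buffering rates (20 and 60 /AU/h)
  keep free BH3-only levels far below the Bax/Bak activation scale while
  Bcl2 persists.
- **Caspase-3 arm**: conversion by cytochrome c is fast (pool converted in
  tens of minutes after MOMP), so every MOMP scenario reaches the same
  pool-limited maximum (≈ conversion total − XIAP) — this is why TNF+ActD,
  TNF+CHX and sensitizing agree to well under 1% without any tuning tied to
  that comparison, and why in the XIAP knockout FasL alone is nearly as
  lethal as FasL after sensitizing ("not further enhanced", operationalized
  as ≤ 1.2×).

## Numerics

LSODA with rtol 1e-7 / atol 1e-9; the ROS-pulse edges and the FasL onset are
integration breakpoints; MOMP is localized by the solver's event root-finder
and applied as a state jump, after which integration restarts (the event is
latched). Output is a dense grid of 0.01 h. States are clipped at zero when
evaluating rates; the public right-hand-side functions reject materially
negative inputs with a diagnostic. Halving the tolerances moves the 8-h
total-JNK readout by < 0.1%. The resting composite state (core rest ⊕ NF-κB
steady state) is cached per NF-κB parameter set.

## Sensitivity, robustness, classification

Local sensitivities are central finite differences of log-outputs with
respect to log-parameters (default relative step 0.01) for pJNK at 8 h, the
pre-MOMP maximum of activated Bax/Bak, and caspase-3 at 10 h; outputs that
are identically zero are flagged and reported on an absolute scale instead.
Robustness scans rerun the scenario battery at multiplicative factors
spanning 1e-2..1e2 and declare a parameter robust only if the full
seven-constraint profile holds at every factor. The caspase-3 classifier is
relative: *none* below 5% and *high* from 60% of the TNF+ActD maximum under
the same parameter set; the cut points are conventions of this package (the
underlying claims are ordinal).

## Synthetic data

The generator emulates the study's readout types from model trajectories:
DEVDase caspase-3/-7 fold over control (C3 over a baseline floor of 1% of
the TNF+ActD maximum), DCF ROS fold over control (against an assumed
constitutive background of 10 AU), Western-blot densitometry (species sums
times a gain; gain 1 makes the resting JNK pool read 100), and qRT-PCR
2^-ΔΔCT transcript fold over the untreated level. Replicate noise is
multiplicative log-normal — fold-scale assays are strictly positive with
signal-proportional scatter — with σ defaults of 0.1 chosen as a typical
between-replicate spread for such assays (the study reports only mean ± s.d.
error bars, no numeric noise magnitudes). What passing recovery tests show is
that the estimation machinery is consistent and well-conditioned for the
chosen designs; they do not show that real blots or plate assays carry this
noise structure, nor do the emulated readouts model saturation, background
subtraction or loading-control artefacts.

Parameter recovery minimizes squared log-residuals with a trust-region
least-squares solver in log-parameter space (finite-difference step 1e-3,
large enough to dominate the integrator's noise floor). Zero-noise data
return an identifiable ground truth to numerical precision; at σ = 0.1 with
three replicates the single-parameter estimate stays within a few percent.

## Known limitations

- **Depth of the first pJNK termination.** The early pJNK peak (at ~0.3 h)
  drops about two-fold by 1 h and decays slowly thereafter; it does not fall
  below ~25% of its peak by 1 h under any admissible constants. This is
  structural, not a tuning failure: the MKK7 drive (complex1) cannot decay
  faster than the 0.05/h conversion of complex0 allows, so the drive
  persists, and a single linear pJNK→phosphatase feedback cannot grow more
  than ~3-fold between the peak and 1 h because its own driver collapses
  with the peak. A global search over the five loop constants puts the floor
  of the 1 h/peak ratio at ≈ 0.24. The qualitative picture — one early peak,
  termination to a small tail, no second phase without ROS — holds.
- ROS release is a prescribed pulse, not a mechanistic model of
  mitochondrial ROS-induced ROS release; stimuli are Boolean, so there is no
  dose–response; kinetics are deterministic mass action in arbitrary units
  (the parameters are phenomenological, not elementary rate constants); no
  spatial effects; partial MOMP does not exist (the release is all-or-none).
- The NF-κB module constants are a transcription of the published module
  validated behaviourally (oscillations, early activation, conservation,
  resting distribution), not against the original table.
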