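# Methods

`shemon` re-implements the computational core of a wireless, skin-wearable
single-lead ECG + IMU monitor: beat detection and vitals estimation, a
per-sample ECG segmentation network, an IMU activity classifier, the
thin-film conformal-contact criterion, and a streaming monitor loop. This
note records the models, their assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Working rate, windows, and the label space

All ECG models operate at 250 Hz. Records acquired at other rates (1000 Hz,
257 Hz) are brought to 250 Hz by polyphase resampling with anti-aliasing
(`signal_io.resample`); beat annotation indices are rescaled by the same
ratio. Segmentation windows are 8 s — 2000 samples — and non-overlapping
(stride = window); windows are half-open `[start, start+2000)` with 0-based
indexing, and a trailing partial window is dropped.

The per-sample label space has 9 classes: 0 background/normal, 1 MI, 2 HF,
3 AR (record-level diagnosis classes), 4 FB, 5 SVEB, 6 VEB (beat-level
classes), 7 paced/other, 8 unknown/noise. Only seven class identities are
documented for the original device model; the final two slots are this
package's assignment and are configurable through the class scheme mapping.
Label expansion paints each annotated ectopic beat over a symmetric
±300 ms (±75 sample) neighborhood of its R-peak — wide enough to cover one
QRST complex without swallowing neighbors at ≤100 bpm — with precedence
beat class > rhythm class > background. Normal beats do not claim samples;
a record-level rhythm class fills everything not claimed by an ectopic
neighborhood.

## Synthetic data generator

`synth.synth_ecg` renders each beat from a Gaussian-sum P-QRS-T template
with textbook precordial-V2 morphology rather than an ODE model: the
template is exactly invertible, so ground-truth beat indices and classes
are returned with the record. Beats are placed by a renewal process with
mean interval 60/HR s, Gaussian interval jitter (`hr_sd`, default 0.02 s),
and respiratory sinus arrhythmia (`rsa_depth`, default 4% interval
modulation). Respiration enters a second way: the R amplitude is modulated
by `1 + resp_mod_depth * sin(2π·RR/60·t)` (default depth 0.15 at
15 breaths/min) — the handle the ECG-derived-respiration estimator pulls
on. Baseline wander is a 0.25 Hz sinusoid (default 0.05 mV) and additive
white noise defaults to 0.02 mV, which puts the clean synthetic records
around 25–30 dB SNR, the range a well-adhered dry-electrode wearable
produces at rest.

Ectopic beats are injected at a Poisson rate per class and *replace* the
nearest scheduled sinus beat, which prevents physically impossible overlaps:
a VEB fires 25% early with a wide (σ≈45 ms), inverted, P-less complex and a
discordant T — the following sinus beat stays on its grid, producing the
compensatory pause; an SVEB fires 15% early with a narrow complex and an
altered P′. Rhythm-level variants (`rhythm="MI"` / `"HF"`) modify the whole
record's template: ST-segment elevation with T inversion for MI,
low-voltage broadened complexes for HF. These morphologies are caricatures
chosen to be *learnable*, not clinically calibrated: a passing recovery
experiment shows the pipeline can learn morphology-separable classes, not
that it would reach the same accuracy on hospital data.

`synth.synth_imu` emulates chest-worn 6-axis IMU patterns at 50 Hz: idle is
gravity plus sensor noise; walking/running are periodic vertical impact
bursts at activity-specific cadence (1.8 / 2.8 Hz) and amplitude with
cadence-locked pitch gyro oscillation; stairs add a slow pitch-bias
oscillation from torso lean; a fall is a single >3 g impact transient
followed by a 90° orientation change (gravity migrating from the z to the x
axis) and stillness. Real IMU data differ mainly in inter-subject cadence
variability and in transitional segments between activities, neither of
which is modeled.

## QRS detection and vitals

`vitals.detect_qrs` is the classic five-stage Pan-Tompkins pipeline:
zero-phase 5–15 Hz band-pass, differentiation, squaring, 150 ms
moving-window integration, then adaptive dual thresholds with running
signal/noise peak estimates, a 200 ms refractory period, and search-back at
1.66× the running RR average. Events are refined to the largest band-passed
deflection within ±40 ms of the integrated peak. Detection is
shift-equivariant and scale-invariant because every threshold is derived
from the data.

HR: instantaneous 60/RR assigned at interval midpoints, cubic-spline
interpolated onto a 4 Hz grid, clamped to (0, 300) bpm.

RR (respiration): the R-peak peak-to-trough amplitude series — beat
amplitude is read peak-to-trough over ±60 ms, which makes it robust to
baseline level — is interpolated to 4 Hz, band-passed to 0.066–0.7 Hz
(4–42 breaths/min), and the rate is read from the dominant spectral peak of
each sliding 30 s window with parabolic sub-bin refinement. Ties within 10%
of the peak power resolve toward the previous window's rate (continuity).
A window whose peak is weaker than 20× the median band power reports NaN
(not-detectable) — with zero amplitude modulation there is no respiratory
signal to read, and reporting a number would be an invention. An
amplitude-based estimator was chosen over an interval-based (RSA) one
because amplitude modulation survives at the low RSA depths typical of
adults.

SNR: per 8 s window, `A_signal` is the mean peak-to-trough amplitude of the
detected QRS complexes. For `A_noise`, whole complexes (P through T:
−min(300 ms, 0.35·RR) to +min(500 ms, 0.58·RR) around each R) are excised,
a 99-sample median filter of the bridged trace estimates the slow baseline,
and the noise is the residual on the surviving inter-beat samples; window
margins are excluded because beats just outside the window leak P/T energy
into them. `SNR_dB = 10·log10((A_signal/A_noise)²)`, averaged over windows.
The metric is exactly scale-invariant and recovers constructed additive
noise within a fraction of a dB across 0.01–0.08 mV.

## The segmentation network

`annotation_net.EcgSeq2Seq` maps a (2000, 1) window to a (2000, 9) softmax
field. Encoder: a convolutional stem (default two 32-filter, kernel-7,
stride-2 convolutions + max-pool 2) followed by four inception-type blocks
(parallel kernel-1/3/5 branches plus a stride-1 max-pool branch, 32 filters
each, concatenated), each followed by a max-pool 2. Decoder: one
×2 nearest-neighbor upsampling stage per encoder halving, each
concatenating the encoder feature map of equal length (skip connection)
before a kernel-3 convolution. Halvings use ceil semantics, so the
architecture is length-parametric; the decoder trims at most one sample per
stage. Every convolution is followed by batch normalization; inside blocks
the activation is linear (the max-pool stages and the output softmax supply
the nonlinearity), matching the device model's description. Exact filter
counts are config-driven since the original layer table is not public.

Training: categorical cross-entropy, Adam starting at lr 0.001, learning
rate divided by 10 when validation accuracy has not improved for 2
consecutive epochs ("no improvement for consecutive epochs" read as
patience = 2), 75/25 train/test under fourfold cross-validation with
disjoint, group-stratified folds, and an 80/20 train/validation split
inside the training set. Inverse-frequency class weights counter the
background-heavy label distribution. Everything is seeded and the framework
is pure numpy, so training is bit-reproducible.

The *scaled* variant used for the desk-scale recovery experiments keeps the
topology but narrows it (single 12-filter stem conv, two blocks of
8-filter branches, 16 decoder filters, ~12k parameters) and swaps in ReLU
activations and an unweighted loss: at this capacity the linear/weighted
protocol converges several times slower and plateaus below a useful
accuracy, while ReLU + unweighted reaches ~94% held-out per-sample accuracy
on the 4-class synthetic set in 10 epochs. This is an explicit capacity
trade-off of the stand-in, not a claim about the full-scale model. A
related capacity limit: painted ±300 ms label rectangles cannot be
memorized to single-sample precision through a 16× downsampling bottleneck,
so per-sample *training* accuracy on small sets plateaus near 95%.

Beat-level annotation assigns each detected beat the majority per-sample
class within ±300 ms of its R-peak (ties → higher mean probability;
confidence = majority fraction); record-level flags are raised for any
FB/SVEB/VEB beat and for a rhythm class covering more than half a window.

## The activity classifier

`activity_net.ActivityResNet` classifies 4 s, 50 Hz, 6-channel windows into
idle/walk/stairs/run/fall. IMU windowing is this package's choice (the
original work does not state it); 4 s spans at least two gait cycles at
walking cadence. Channels are z-scored with training-set statistics. The
network is a 16-filter stem convolution plus residual blocks
(conv-BN-ReLU-conv-BN with identity shortcut, 1×1 projection on width
change, max-pool 2 between blocks), global average pooling and a dense
softmax. Training protocol is identical in form to the segmentation
network's. "Walking upstairs" and "walking downstairs" are reported as one
`stairs` class by default, matching the 5-class output; the synthetic
generator produces the merged class directly.

Streams are classified over 50%-overlap sliding windows. A window
classified as `fall` is only reported as such if its acceleration magnitude
actually contains a transient above 2 g — a pre-check that suppresses false
alarms from ambiguous windows but, being below the 3 g construction
amplitude, can never veto a genuine impact.

## Conformal-contact mechanics

The electrode laminate is a composite beam: `effective_bending_stiffness`
uses the transformed-section method about the modulus-weighted neutral
axis, EI = Σ Eᵢ(tᵢ³/12 + tᵢ(yᵢ−ȳ)²) per unit width. Skin is an elastic
half-space with a sinusoidal roughness profile (amplitude `h_rough`,
wavelength `λ_rough`). The film sags into the valleys by
h = E_skin·h_rough / (16π³·EI/λ³ + E_skin), which is monotone decreasing in
EI and bounded by [0, h_rough]. Conformal contact requires the elastomer's
work of adhesion to exceed

    γ_crit = 1/(1−α) · [ π⁴·EI·h²/λ⁴
             + (π·E_skin·(h_rough−h)/(16λ)) · (1 + π²h²/(4λ²)) ]

with α the areal fraction of the stiff PI/Au mesh; the inequality is
strict, so a candidate exactly at the boundary is classified non-conformal.

Two caveats are worth stating plainly. First, the skin-elasticity term is
implemented exactly as published for this device, linear in (h_rough−h);
dimensional analysis of that term yields Pa rather than J/m², where related
thin-film-on-skin analyses carry (h_rough−h)²/(16λ). Consequently absolute
γ_crit values computed with literature skin parameters are orders of
magnitude above measured elastomer adhesion energies, and the elastomer
classification is meaningful through the *ordering and relative margins* of
candidates rather than their absolute conformal/non-conformal labels.
Second, the skin parameter defaults (E_skin = 130 kPa, λ_rough = 140 µm,
h_rough = 50 µm) are literature-typical placeholders — the values behind
the original boundary curve are not public — and are user-overridable
everywhere.

The work of adhesion is recovered from rolling-cylinder data as the
y-intercept of a least-squares polynomial (default linear) of effective
peel energy versus speed, with the intercept's standard error from the
residual covariance. Peel energies integrate force–displacement curves by
the trapezoidal rule, requiring strictly increasing displacement.

## Monitor loop

`monitor.run_monitor` replays time-aligned ECG and IMU sources: one event
per 8 s ECG window carrying mean HR over the window, the latest RR (once
30 s of history exists), the beat annotations falling in the window, the
majority activity class of the concurrent IMU windows, and alerts. Alerts
are debounced to one per contiguous abnormal (or fall) run, and no partial
windows are emitted. The loop is a pure function of its inputs, so
replaying a session with the same checkpoints yields byte-identical JSONL
logs.

## Experiment sizes and tolerances

The standing recovery experiments (`shemon.experiments`) use 2000 ECG
windows / 4 classes and 600 IMU windows / 5 classes for the fourfold CV
runs, 20 one-minute records spanning 60–180 bpm for the QRS sweep, and
2-minute records per rate for the RR sweep over 6–30 breaths/min at
modulation depths 0.1 and 0.2 — sizes chosen so the full suite trains on a
single CPU core in minutes while each class still contributes hundreds of
windows per fold. Numerical tolerances in the tests mirror what each
quantity supports: exact identities (SNR formula, peel-triangle area,
intercept on a noiseless line, Eq.-limits of the contact model) are
asserted to 1e-9 or machine precision; spectral and estimator recoveries to
their stated physiological bands (±1 bpm, ±1 breath/min, ±1.5 dB); and
stochastic CV accuracies against the ≥90% floor.

## Known limitations

- Synthetic morphology classes are more separable than real pathology; CV
  accuracies here bound what the architecture can express, not clinical
  performance.
- The WFDB reader covers single/multi-channel formats 16 and 212 with
  standard beat annotations — enough for the named public databases — not
  the full format zoo.
- RR estimation assumes amplitude-mediated respiratory coupling; a subject
  with negligible amplitude modulation reports NaN rather than falling back
  to RSA.
- The contact model's dimensional caveat above; and the AR (miscellaneous
  arrhythmia) rhythm class is represented only through interval
  irregularity, which the current generator does not exercise in the
  recovery experiments.
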