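# Methods

## Model and assumptions

Renal clearance is modelled as two additive pathways. Glomerular
filtration is restrictive: `CL_GF = fu · GFR`, so only unbound drug is
filtered. Active tubular secretion uses a well-stirred kidney term driven
by the post-glomerular blood flow,

    CL_ATS = (Qr − GFR) · fu · CL_int_sec / (Qr + fu · CL_int_sec / BP),

which interpolates between a permeability/transport-limited regime
(`CL_ATS ≈ (Qr − GFR)·fu·CL_int_sec/Qr` for small intrinsic clearance) and
a flow-limited ceiling (`CL_ATS → (Qr − GFR)·BP` as intrinsic clearance
grows; the ceiling is never attained for finite inputs). The model
excludes tubular reabsorption, renal metabolism and any pH/ionisation
effects, and simulates clearance only — no concentration–time profiles.

Whole-kidney intrinsic secretion clearance is the plain product

    CL_int_sec = CL_int_ATS · kidney weight · PTCPGK · rTA,

converted µl·min⁻¹ → L·h⁻¹ (× 60/10⁶). PTCPGK (99.4, per gram kidney) is
a proximal-tubule scaling factor taken from a commercial PBPK platform and
held BMI-invariant. Its per-gram-kidney semantics against the
per-mg-protein units of CL_int_ATS are applied exactly as the product
formula states and deliberately not reinterpreted; CL_int_sec values are
therefore meaningful relative to each other rather than as absolute
proximal-tubule transport rates.

Two composite rescalings couple drug to subject:

* **Unbound fraction.** Binding is linear (non-saturable) with constant
  affinity, so `fu = 1/(1 + Ka·[P])` and the closed form
  `fu = fu_nw / (fu_nw + (1 − fu_nw)·r)` with `r` the binding-protein
  concentration ratio vs the normal-weight subject. Strictly decreasing in
  `r`; a drug with `fu_nw = 1` does not bind and is unaffected. Each drug
  binds exclusively one protein (HSA or AAG).
* **Blood-to-plasma ratio.** The hematocrit-weighted partition identity
  `BP = 1 + Hct·(fu·Kp − 1)`; hematocrit 0 gives BP = 1 and BP is bounded
  below by 1 − Hct. Kp and affinity are BMI-invariant.

## Virtual subjects

Subjects are *typical*: one deterministic profile per BMI category
(defaults 20, 25, 30, 40, 50, 60 kg/m²), height fixed at 1.72 m (an adult
median), bodyweight = BMI·height² (59.2–177.5 kg; reported to one decimal,
unrounded internally). Sex defaults to male and only gates hematocrit in
the shipped set; it is configurable. No inter-individual variability is
modelled — conclusions are about typical subjects, not populations.

Physiology comes from a pluggable parameter-set registry mapping
(BMI, sex) → {GFR, Qr, kidney weight, [HSA], [AAG], hematocrit}. The
shipped `fixture_linear` set is synthetic plumbing, not literature
physiology: linear trends in bodyweight chosen to exercise every model
property (GFR 6.5 + 0.04·(BW − 59.2) L/h, Qr 60 + 0.25·(BW − 59.2) L/h,
kidney weight 300 + 1.5·(BW − 59.2) g, HSA 45 − 0.03·(BW − 59.2) g/L,
AAG 0.8 + 0.004·(BW − 59.2) g/L, hematocrit 0.45 male / 0.40 female).
It reproduces the qualitative obesity signature — GFR, renal blood flow,
kidney weight and AAG rise; HSA falls; hematocrit is sex-only — with
realistic magnitudes, but its numerical outputs (e.g. required-exponent
extrema) are properties of the fixture, not of published obesity
physiology. Tests passing on the fixture demonstrate the correctness of
the model algebra, the pipeline bookkeeping and every structural
invariant; they do not certify quantitative claims about real obese
subjects. Published coefficient tables (e.g. a transcription of the Berton
et al. obesity repository, conventionally registered as `berton2022`) can
be loaded from YAML (`load_parameter_set`), which supports constant,
per-sex, linear-in-bodyweight, linear-in-BMI, power and polynomial forms;
the package does not bundle coefficients it cannot source.

A small nuance, followed deliberately: the fixture coefficients are
written against the rounded reference weight 59.2 kg while the pipeline
uses the exact weight (59.168 kg at BMI 20), so baseline fixture values
sit within 0.2 % of their nominal intercepts.

## Study design

The drug space is a full factorial grid (no sampling): fu ∈ {5, 25, 50,
75, 95, 100 %} × Kp ∈ {0.35, 1, 2, 3, 4, 5, 10, 20, 30, 40} × CL_int_ATS ∈
32 arithmetically equidistant values on [2, 500] µl·min⁻¹·mg⁻¹ (step
498/31; equidistant means linear, not log, spacing) × rTA ∈ {20, 50, 100,
150, 200, 250 %} = 11,520 combinations, evaluated as two parallel runs
(HSA, AAG) across the six BMI categories — 138,240 clearance rows, which
evaluate vectorised in under a second. rTA is defined relative to normal
weight, so the baseline subject always sits at rTA = 1; the baseline
clearance for relative CLr and for scaling uses BMI 20 with rTA = 1.

Scaling evaluation: `scaled CLr = CLr_normal · (BW_obese/BW_normal)^e` for
each configured exponent (defaults 0 and 0.75), signed prediction error
`PE = 100·(scaled − PBPK)/PBPK`, accuracy |PE| ≤ 30 % with an **inclusive**
boundary (the threshold is configurable), and the exactly-scaling exponent
`ln(CLr_obese/CLr_normal)/ln(BW_obese/BW_normal)` (natural logs; undefined
at equal bodyweights, which is rejected). Systematic accuracy is
all-or-nothing per stratum; default strata are BMI × rTA × binding protein
× fu × CL_int_ATS (Kp left free inside each stratum), and verdicts can be
regrouped over any key subset.

## Numerical and design choices

* Canonical units everywhere internally: L, h, g, g/L; conversions only at
  module boundaries. Clearances never go negative; `fu = 0` and
  `rTA = 0` degenerate gracefully to pure-filtration results even though
  the default grid excludes them.
* Zero total clearance makes pathway contributions undefined; they are
  reported as missing, never as 0/0 artefacts.
* Validation is eager and names the offending parameter (e.g. a physiology
  function returning a non-positive value, Qr ≤ GFR, hematocrit outside
  [0, 1)). BMI outside [20, 60] warns (extrapolation) rather than fails.
* The pipeline contains no randomness; runs are byte-identical for
  identical configurations. CSV output is UTF-8, comma-delimited, '.'
  decimal, empty missing values, floats at 6 significant digits.
* Grid enumeration order is fixed (first axis slowest, last fastest) so
  tables are reproducible byte for byte; permuting axis order changes row
  order only, never the row set.
* The ±30 % band, the exponent list and all grid axes are configuration,
  not constants; the defaults are the study conditions above.
* Figure generation was left out; the delimited tables are the output
  surface and plot trivially with any tool.

## Limitations

* Quantitative statements tied to published obesity physiology (e.g.
  required-exponent extrema under the Berton equations) can only be
  reproduced after registering that coefficient table; the shipped fixture
  supports structural verification only.
* Typical-subject design: no variability, no covariates beyond BMI/sex,
  no paediatric or renal-impairment physiology.
* The two-pathway model bounds its own applicability: drugs with material
  reabsorption or renal metabolism fall outside it.
* Hypothetical drug combinations near the grid corners (e.g. fu = 100 %
  with maximal secretion) may be pharmacologically implausible; the grid
  is a coverage device, not a drug library.
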