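# Methods

## Scope and intent

chromofiber implements the *scoring* chain of mechanistic DNA-damage
simulation: a volumetric chromatin-fiber target, a parametric generator of
energy-deposition events emulating proton track structure, energy-threshold
strand-break induction, bp-distance damage clustering with complexity
classification, and single-event microdosimetry. Physical particle
transport (cross-sections, elastic/inelastic models, chemistry, indirect
damage) is deliberately outside the package: the track generator is a
statistical emulator whose parameters are exposed, not derived from
physics.

## Geometry

All lengths are nm; the fiber frame has z along the fiber axis and its
origin at the fiber center.

* **Nucleotide pair.** One rigid frame per bp. Consecutive pairs along a
  straight segment differ by a 0.34 nm rise and a 36° twist about the local
  helix axis. In the bp frame, strand s ∈ {0,1} owns a backbone volume
  (annular 90° sector, radii 0.5–1.15 nm, thickness 0.34 nm, centered on
  azimuth s·180°) and a base volume (half-disc of radius 0.5 nm on the same
  side). The two backbone sectors being 180° apart is a convention — the
  model carries no groove asymmetry — and the exact sector azimuth is fixed
  by the twist transform.
* **Nucleosome.** The DNA path is a left-handed helix of 1.65 turns at
  radius 4.45 nm (histone radius 3.3 + backbone radius 1.15) with pitch
  5.7 nm/1.65 turns, i.e. the wrap spans the histone height. Frames sit at
  0.34 nm arc spacing: 137 wrapped bp (round(46.49 nm/0.34)). Frame
  orientation uses the radial-outward reference direction plus the
  accumulated 36°/bp twist about the local tangent.
* **Linker.** A cubic Bézier joins the wrap exit of one nucleosome to the
  entry of the next with continuous position and tangent (handle length =
  chord/3). 40 linker frames are placed at equal arc spacing including both
  end frames; frames are parallel-transported (rotation-minimizing),
  twisted 36°/bp, and the residual roll against the far end is distributed
  linearly so the last frame matches exactly. If the implied spacing
  deviates from 0.34 nm by more than 0.05 nm the linker is rejected as
  geometrically infeasible. The default wrap start azimuth (322°) was
  chosen by a geometric scan so the default fiber's linkers come out at
  0.340 nm spacing.
* **Fiber.** 61 nucleosome centers on a solenoid helix of radius 11.5 nm,
  60° of fiber azimuth per nucleosome (6 per turn), axes tangent to the
  helix. The axial span leaves a 6.5 nm clearance at each fiber end so that
  every nucleotide volume provably stays inside the 37 × 161 nm envelope
  (checked at build time; violation raises an error). The printed fiber
  length (161 nm) is used for the 4.2-per-11 nm density regardless of the
  internal clearance. The per-unit allocation 137 wrapped + 40 linker
  = 177 bp — a typical somatic nucleosome repeat — makes the total
  61 × 177 = 10,797 bp ≈ 10.8 kbp. The 61st linker trails toward the
  solenoid's virtual next nucleosome so every unit is identical.
* **Point→volume queries.** A k-d tree over bp frame origins supplies
  candidate volumes within the bp bounding radius; candidates are tested
  analytically in their local frames. Priority backbone > base > histone >
  water, ties broken on lowest (bp index, strand): deterministic, and
  verified against an exhaustive all-volume scan in the tests.
* **Nucleus envelope.** A cylinder with ellipsoidal base (semi-axes
  9.85 µm and 7.1 µm, height 2.5 µm; ~6×10⁹ bp) is provided as a
  normalization construct only. Its computed bp density is
  6e9/(π·a·b·h) = 0.0109 bp/nm³.

## Synthetic track structure

Each primary history is a straight chord through the scoring cylinder
(isotropic uniform randomness: isotropic direction plus uniform offset on
the perpendicular disc of the bounding sphere) — adequate for MeV protons,
which scatter negligibly over 161 nm. Interaction sites form a Poisson
process along the chord at rate `deposits_per_nm / cluster_size_mean`; each
site spawns Poisson(`cluster_size_mean`) deposits displaced by an isotropic
Gaussian of scale `radial_sigma_nm`, so the mean linear deposit density is
`deposits_per_nm`. Each history owns an RNG stream seeded from
(seed, history id), making ensembles reproducible independent of execution
order.

Defaults (chosen once, as the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_tracks` | 1000 | ensemble size giving sub-minute runs with usable DSB statistics |
| `deposits_per_nm` | 3.0 | with a ~15 eV mean deposit this is ~45 eV/nm, the LET scale of ~0.5–1 MeV protons |
| `cluster_size_mean` | 5.0 | deposits per interaction site; track-end secondary electrons deposit in compact clusters |
| `radial_sigma_nm` | 1.0 | nanometre lateral spread of those clusters, commensurate with the 2.3 nm helix diameter |

The per-deposit energy spectrum is a mixture: 75% truncated normal
(mean 11 eV, σ 3 eV, support 1–17.5 eV; excitation-like) and 25%
exponential tail 12.6 eV + Exp(15 eV) (ionization-like). This satisfies the
two qualitative constraints the model is designed around — most single
deposits fall below 17.5 eV (P ≈ 0.8, validated analytically at
construction), and little single-deposit mass lies between 17.5 and
21.25 eV, so damage scored at those two thresholds differs mainly through
multi-deposit accumulation and stays close.

What the generator does *not* emulate: energy-dependent cross-sections,
delta-ray range and angular structure, track-end Bragg-peak densification
along one chord, and any chemistry. Consequently the package's absolute
yields are not predictions for a specific proton energy; the meaningful
outputs are orderings, ratios and sensitivities of the scoring chain, which
are insensitive to those omissions by construction.

## Damage induction

Energy is accumulated per backbone volume per primary history *before*
applying the threshold (the models act on total energy deposition, and
per-history binning prevents cross-track accumulation). Deposits in base,
histone or water volumes contribute nothing: base damage is out of scope.
Constant thresholds are boundary-inclusive (thresholds are physical onset
energies) and deterministic; the linear ramp P = (E−5)/32.5 clipped to
[0,1] is sampled with a seeded generator. A backbone volume breaks at most
once per history.

Two exact consequences used as test oracles: breaks(T₂) ⊆ breaks(T₁) for
T₁ < T₂, and the expected linear-model break count is bracketed by the
counts at constant 37.5 and constant 5 eV.

## Clustering and classification

Clustering is strand-blind single linkage on bp distance within one
history; in one dimension this is gap-splitting of the sorted break list
and provably equals all-pairs connected components. Classification then
inspects strands (SSB, SSB+, DSB, DSB+, DSB++). Two conventions are worth
stating:

* A mixed-strand cluster always contains an opposite-strand pair within
  n bp (some edge of its connecting chain joins opposite strands), so
  "2SSB" — opposite-strand breaks farther apart than n bp — is only
  possible across clusters and is reported as a derived per-history
  statistic, not a cluster label.
* The DSB multiplicity of a cluster is min(per-strand break counts): the
  size of a maximal disjoint opposite-strand pairing, treating the cluster
  itself as the segment. This makes TSB = SSB breaks + 2·DSB an identity
  and makes the DSB count monotone both in added breaks and in the
  clustering distance (merging two clusters can only raise min(n₀,n₁)).

The SSB/DSB ratio is reported as None/omitted when no DSB was scored,
rather than infinity.

## Microdosimetry

Spheres of diameter 2.3, 10 and 30 nm (helix, nucleosome, fiber scales) are
anchored at a uniformly chosen deposit plus an isotropic offset of length
uniform in [0, d/2), so each sphere contains its anchor. ε sums one
history's deposits inside one sphere; y = ε/(2d/3). y_F and y_D are sample
moments rather than histogram integrals (the defining expressions are
expectations; a log-binned histogram with 40 bins/decade is provided for
plotting only). eV/nm and keV/µm are numerically identical.

Scale dependence is regime-dependent: when spheres capture isolated deposit
clusters (sparse tracks), larger spheres dilute ε over a longer mean chord
and y_F, y_D fall with d; for through-going chords at the default LET,
ε grows ∝ d and y_F is roughly size-independent. The property tests
exercise the sparse regime explicitly.

## Pipeline, seeds, uncertainty

`run_once` chains tracks → accumulate → induce → cluster → tally (+
microdosimetry), logs one structured line per stage, and writes TSV/CSV
artifacts plus a config snapshot and manifest when an output directory is
set. All child seeds derive from `base_seed` via SeedSequence spawning and
stay below 2³¹. Yields are normalized per Gy per Gbp with the fiber
envelope's water mass and the fiber's 10,797 bp; nucleus-scale numbers are
a documented multiplication by the nucleus/fiber bp ratio, never a
simulation.

`sweep_et_models` scores all constant thresholds and the linear model on
one shared event set (the constant models are then deterministic);
`sweep_cluster_distance` re-clusters one shared break set at every
distance. `uncertainty_report` computes per-cell relative standard errors
(sd/√n/mean) and flags cells above a bound (default 3%); the acceptance
script grows the repeat count until the report stops flagging, which lands
at ≈ 50–120 repeats of the default ensemble for the 3% bound on the SSB
yield, DSB yield and their ratio.

## Numerical choices and degenerate inputs

* Linker arc length and transported frames use 40·n dense Bézier samples;
  positions at the equal-arc targets are evaluated analytically at
  interpolated parameters (no grid snapping).
* Containment tolerances are exact inequalities in double precision; the
  k-d-tree query radius carries a +1e-9 guard.
* Empty inputs: zero deposit rate yields an empty (typed) event table and
  an empty tally dict (dose 0 cannot normalize); empty break lists cluster
  to nothing; spectrum statistics on zero samples raise an undefined-result
  error rather than returning NaN.
* `read_events` rejects non-numeric, non-finite or non-positive-energy rows
  naming the offending line.

## Known limitations

* No physics transport: absolute yields track the synthetic ensemble's
  parameters, not a proton energy axis.
* Backbone-only scoring; no base damage, no indirect (radical) damage, no
  histone scavenging.
* One fiber in vacuo — no nucleus-scale chromatin instantiation, no
  heterochromatin/euchromatin variants, no fragment-size spectra.
* The geometry is a convention-complete volumetric model, not atomistic;
  sector azimuths and the backbone "deleted section" follow the documented
  conventions above.
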