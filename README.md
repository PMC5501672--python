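# porexlink

Pore-radius profiling, cysteine cross-link span prediction and
conformer-ensemble comparison for ion-channel structural models.

## The problem

Structural models of ion channels — for instance the outward-facing (OWF,
conducting) and inward-facing (IWF, non-conducting) conformations of an
ABC-family chloride channel such as CFTR — need quantitative, testable
consequences before they can be trusted.  Three kinds of evidence are
standard:

1. **Pore geometry.**  The pore radius R_pore(z) along the channel axis,
   defined at each axial position z as the radius of the largest probe
   sphere centred in that plane touching no atom:

       R_pore(z) = max_p  min_i ( |p − x_i| − r_i )

   over in-plane probe centres p and atoms i with van der Waals radii r_i.
   A conducting state must hold R_pore at or above the hydrated Cl⁻ radius
   (~1.6–1.9 Å) through its narrowest point (the selectivity filter); a
   non-conducting state pinches below it.

2. **Pairwise distance restraints from cysteine cross-linking.**  A
   bifunctional methanethiosulfonate reagent MnM with an n-methylene spacer
   covalently bridges two substituted cysteines when their Cβ–Cβ distance d
   lies inside the reagent's span window.  The package uses the linear
   spacer model `span_max(n) = 2.6 + 1.3·n` Å — exactly reproducing the
   M3M (6.5 Å), M8M (13 Å) and M17M (24.7 Å) anchors — with
   `span_min = span_max/2` for chain fold-back.  Comparing per-conformer
   mean distances from an ensemble with observed cross-linking outcomes
   gives a per-pair concordance verdict, and conformer-resolved predictions
   say *which* state a reagent traps.

3. **Ensemble behaviour.**  Kabsch superposition RMSD against references,
   RMSD-vs-time plateau detection for equilibration, and quality-threshold
   clustering of trajectory frames at a 2 Å backbone RMSD radius with
   centroid representatives.

`porexlink` implements all three, end to end, over multi-model PDB files
treated as conformer ensembles — plus a synthetic-data generator that builds
helix-bundle channels with *analytically known* pore radii and reporter
distances, so the whole pipeline is testable without any external data.

## Worked example

```sh
python examples/01_pore_profile.py
```

prints

```
  open state: narrowest radius 2.50 Å at z=+0.0 Å (analytic truth 2.50 Å) -> open
closed state: narrowest radius 0.80 Å at z=+0.0 Å (analytic truth 0.80 Å) -> closed
```

i.e. the probe-sphere walk recovers the generator's analytic filter radius
in both conformations, and the hydrated-Cl⁻ criterion classifies the open
state conducting and the closed state non-conducting.  The other examples
show conformer-resolved cross-link prediction (`02`), the
simulation/concordance closed loop (`03`) and equilibration detection plus
clustering (`04`).

From Python, the same computation is three calls:

```python
from porexlink import ProfileParams, ensemble_profile, locate_minimum
from porexlink.synthetic_data import channel_segment_map, default_channel_spec, make_channel

spec = default_channel_spec()
ensemble, truth = make_channel(spec, "open")
profile = ensemble_profile(ensemble, ProfileParams(seed=1),
                           segment_map=channel_segment_map(spec))
print(locate_minimum(profile))   # (0.0, 2.4999...)
```

Real structures enter through `porexlink.read_structure` (multi-model PDB →
`FrameEnsemble`), with segments and membrane windows described by a small
YAML `SegmentMap`.

## Command line

A thin CLI wraps the library:

```sh
porexlink simulate --state open --n-frames 10 --sigma 0.2 --out channel.pdb
porexlink profile --pdb channel.pdb --segments channel.segments.yaml --seed 1
porexlink distances --pdb channel.pdb --pairs pairs.tsv --state OWF
porexlink xlink --distances distances.tsv --obs observations.tsv
porexlink cluster --pdb channel.pdb --threshold 2.0
porexlink run --config run.yaml       # the full pipeline
```

`run.yaml` names the per-state structure files and optional inputs
(`segment_map`, `pairs`, `panel`, `observations`), the output directory and
the analysis parameters; all keys correspond to `porexlink.pipeline.RunConfig`
fields and every default is echoed into the output `report.json`.

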