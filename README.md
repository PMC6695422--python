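# tractlanes

Lane analysis of white-matter fascicles: are two functionally defined sets of
streamlines running through the same fascicle spatially segregated
(parallel "lanes") or intertwined, and do they differ in tissue properties?

`tractlanes` is aimed at diffusion-MRI tractometry work in which cortical
functional regions (fROIs) define subsets of a tractogram. It implements:

- **fWMT extraction** — functionally defined white-matter tracts: the
  streamlines whose endpoints reach a gray-white-matter-interface (GWMI)
  mask under an fROI, plus fascicle **connectivity fingerprints** (the
  percentage of an fROI's fWMT carried by each fascicle).
- **Pairwise connectivity** between two fROIs via the Dice coefficient of
  their streamline connection sets A and B,

  DC = 2 |A ∩ B| / (|A| + |B|),

  with an empirical chance level (mean DC against off-network control ROIs)
  and exclusion of streamlines threading ≥ k ROIs.
- **Tractometry** — orientation, resampling to 100 equally spaced nodes,
  iterative 4-SD outlier cleaning, per-node core (mean) tracts, and
  within-network vs between-network Euclidean distances to the cores.
- **Segregation decoding** — at each node, a linear SVM trained on the
  (x, y, z) coordinates of all streamlines of both groups and tested at the
  node five steps more posterior; balanced accuracy against the 50% chance
  level.
- **Quantitative profiling** — trilinear sampling of co-registered scalar
  maps (e.g. T1 in seconds) along tracts, node profiles, and paired t-tests
  with Bonferroni-adjusted per-node thresholds.
- **Synthetic phantoms** — arched streamline bundles carrying two labelled
  sub-bundles at a configurable centre-to-centre separation, endpoint GWMI
  masks, a control ROI, gross outliers, and a T1-like map with
  lane-specific baselines: ground truth for every stage above.

Streamline I/O is TRK/TCK (via nibabel, normalized to RAS+ world mm),
volumes are NIfTI-1, labels and results are CSV.

## Worked example

```python
from tractlanes import PhantomSpec, generate_phantom
from tractlanes.fwmt import extract_fwmt, pairwise_connection, chance_dc
from tractlanes.segregation import nodewise_classify
from tractlanes.tractometry import (resample_bundle, clean_outliers,
                                    within_between_distances)
from tractlanes.qprofile_stats import tract_profile

phantom = generate_phantom(PhantomSpec(seed=1))   # d = 8 mm lane separation
tracts, masks = phantom.tracts, phantom.gwmi_masks

fwmt = extract_fwmt(tracts, masks["IFG"])
conn = pairwise_connection(tracts, masks["IFG"], masks["SMGr"],
                           names=("IFG", "SMGr"))
bundle, removed = clean_outliers(resample_bundle(tracts))
reading = resample_bundle(tracts.subset(tracts.network == "reading"))
math = resample_bundle(tracts.subset(tracts.network == "math"))
dist = within_between_distances(reading, math)
seg = nodewise_classify(reading, math, lag=5)
t1_r = tract_profile(reading, phantom.scalar_map)
t1_m = tract_profile(math, phantom.scalar_map)
```

prints, with the formatting of the repository's example strings:

```
fWMT of IFG: 102 of 205 streamlines
DC(IFG, SMGr) = 0.971  (A=102, B=104, A∩B=100)
chance DC = 0.000
4-SD cleaning removed 5 streamlines
mean distance to core: within 2.87 mm, between 8.73 mm
node-wise SVM accuracy: 94.0% (chance 50%)
tract-mean T1: reading 0.951 s, math 1.049 s
```

Reading it: the IFG mask captures its 100-streamline lane (plus 2 strays
from the other lane whose endpoints fall in the 5 mm sphere); the two
endpoint ROIs of the same lane share almost all their connections
(DC ≈ 0.97 against a chance DC of 0 from the off-bundle control); the 5
injected gross outliers are exactly the streamlines removed at 4 SD;
streamlines sit ~2.9 mm from their own lane's core but ~8.7 mm from the
other lane's core (the generative separation is 8 mm); lane membership is
decodable from coordinates at 94% (chance 50%); and the lane-specific T1
baselines (0.95 s / 1.05 s) are recovered along the tracts.

A thin CLI mirrors the library: `tractlanes simulate | fwmt | dice |
tractometry | segregate | profile` (see `tractlanes --help`).

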