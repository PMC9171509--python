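# lungalloc

Tools for designing and evaluating geographic organ-allocation policies
built on the **supply/demand ratio**: the number of donor lungs recovered
inside a transplant centre's local allocation unit divided by the number
of transplants the centre performs.

The package models a national geography of organ procurement centres
(OPCs, supply nodes) and lung transplant centres (LTCs, demand nodes) and
provides:

- **`lungalloc.geography`** — centre tables (CSV/GeoJSON), directed
  OPC→LTC travel-time matrices, and travel-time eligibility pools
  (default threshold: 120 minutes, inclusive).
- **`lungalloc.activity`** — supply/demand accounting: unit supply,
  supply/demand ratios, offers per candidate, and dispersion summaries
  (sample or population sd, chosen explicitly).
- **`lungalloc.optimizer`** — the redistricting algorithm: per-LTC
  enumeration of every feasible local allocation unit (size bounds,
  travel threshold, locked members, ratio within a target band) with
  branch-and-bound pruning on supply prefix bounds, followed by an exact
  global search selecting one unit per LTC with pairwise-disjoint OPC
  sets that minimizes the across-centre standard deviation of the
  ratios.  A per-LTC "independent" mode reports overlaps instead of
  resolving them.
- **`lungalloc.offer_sim`** — a per-graft offer-cascade simulator for the
  previous (HU → local → regional → national) and new (HU → local →
  national) schemes, with per-LTC Bernoulli acceptance and Table-style
  equity metrics (tier shares, shipping distance, offers per candidate).
- **`lungalloc.survival`** — non-parametric waitlist and post-transplant
  estimators: Aalen–Johansen cumulative incidence under competing risks
  and the Kaplan–Meier product-limit survivor (point estimates only).
- **`lungalloc.synthetic`** — reproducible scenario generation with
  heterogeneous procurement intensity, skewed historical unit sizes
  (spanning 1–32 OPCs), calibrated waitlist cohorts, and embedded
  printed per-centre table columns as fixtures.

## CLI

One entry point with five subcommands; logging goes to stderr, data to
files, and every output carries a provenance stamp (tool version, seed,
config hash).

```sh
# generate a synthetic scenario
lungalloc synth --n-opc 100 --n-ltc 5 --seed 7 --out-dir data/

# design disjoint local allocation units at a common target ratio
lungalloc optimize --centres data/centres.csv --matrix data/travel.csv \
    --activity data/activity.csv --target 0.5 --tolerance 0.1 \
    --size-min 5 --size-max 15 --max-minutes 120 \
    --out assignment.csv --report report.json

# simulate offer cascades under the new scheme
lungalloc simulate --map assignment.csv --centres data/centres.csv \
    --matrix data/travel.csv --activity data/activity.csv \
    --scheme new --seed 42 --out offers.csv --metrics metrics.json

# waitlist / post-transplant outcome estimates
lungalloc evaluate --waitlist waitlist.csv --posttx posttx.csv \
    --horizon-days 90 --out outcomes.json

# merge the reports
lungalloc report --optimizer-report report.json --metrics metrics.json \
    --outcomes outcomes.json --out summary.json
```

`synth` also accepts a YAML config (`--config scenario.yaml`); explicit
flags win over the file.

## Notes

- Travel times are directed OPC→LTC; synthetic matrices use a straight
  line at constant speed plus optional truncated Gaussian noise, standing
  in for a road-network matrix (road routing is out of scope).
- The global solver is exact over the per-LTC shortlists; when a
  shortlist is truncated (`shortlist_k`) the report flags that the
  optimum is relative to the shortlists.
- Sample-vs-population sd conventions differ between published tables;
  both are supported and always chosen explicitly.
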