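# Methods

## Scope and data model

heatlens implements a desk-scale analysis of public heat perception from
short-text posts. Its inputs are: (a) a post corpus, one record per post
(id, ISO date, region code, UTF-8 text) as JSONL; (b) daily station
summaries in a GSOD-dialect CSV (`STATION`, `DATE`, `MAX` in °F, sentinel
9999.9 for missing); (c) region metadata (per-capita GDP in ten-thousand-
yuan units); (d) a station→region map; (e) optional plain-text stopword
lists. All region-level statistics are computed at provincial-style region
codes; no sub-regional resolution is attempted.

## Text preprocessing

Cleaning removes URLs, user mentions, hashtag markers, emoji codepoints,
advertisement-looking Latin fragments and PII patterns, then normalises
whitespace. PII regexes are deliberately conservative — 11-digit
phone-like runs, 15/18-digit ID-like runs, paired signed decimals
(coordinates) — on the principle that over-removal is acceptable and
under-removal is not. The "advertisement fragment" rule (unbroken
alphanumeric runs of ≥20 characters; three or more consecutive ALL-CAPS
words) is a heuristic: there is no formal definition of ad noise, and the
rule is tuned so ordinary short Latin tokens survive. Cleaning is total
and idempotent.

Heat-post filtering is substring-based and case-folded, with a default
keyword set of five English heat terms ("high temperature", "hot",
"sweating", "heat stroke", "scorching"); any keyword list (e.g. Chinese
equivalents) can be supplied. Substring matching was chosen so the filter
does not depend on segmentation.

Segmentation is an injected `str -> list[str]` callable. The bundled
default splits on whitespace, which is exact for the synthetic vocabulary;
real Chinese text requires an external segmenter plugged into the same
contract. Stopword lists are merged by union, and members with zero
occurrence in a supplied corpus stream are pruned (removal of archaic list
entries). `detect_platform_markers` flags tokens whose document frequency
exceeds a threshold (default 0.30) as candidate platform discourse-marker
stopwords; this simple document-frequency rule is a declared stand-in for
corpus-specific marker extraction, not a TF-IDF method.

## Topic model

LDA with symmetric priors, fitted by collapsed Gibbs sampling. The
conditional for one token, with θ and φ integrated out and counts
excluding that token, is the standard count-ratio form

    p(z = k | z₋, w) ∝ (n_dk + α)(n_kw + β)/(n_k + V β).

Defaults: K = 4, α = 0.1, β = 0.01, 1000 full sweeps when fitting via the
library function (the pipeline default is 200 sweeps, a deliberate
desk-scale setting; on the corpora used here the chain reaches its mode
within a few dozen sweeps). Point estimates of θ and φ are taken from the
final sweep's counts with additive smoothing — no sample averaging — so
every output is a deterministic function of (corpus, K, α, β, iters,
seed).

The collapsed posterior is multimodal: on corpora with one heavy and
several light topics, a chain can get trapped with the heavy topic split
into two near-copies and two light topics merged. The trapped modes sit
far below the dominant one in collapsed log joint (tens of nats per
thousand tokens), so `fit_lda(..., restarts=N)` runs N chains from
deterministically derived seeds and returns the state with the highest log
joint. This keeps bit-reproducibility while making recovery robust; the
pipeline uses 3 restarts by default.

Dominant-topic assignment is argmax of the smoothed document-topic counts
(ties to the lowest topic id). Topic shares are percentages of documents
per dominant topic; the region×topic table gives each region's share of a
topic's documents. Topic labels are arbitrary, so all cross-run
comparisons are made up to label permutation via Hungarian matching on
total-variation distance between topic-word distributions.

## Meteorology

°F→°C conversion is exact arithmetic ((t − 32)·5/9); the sentinel maps to
an explicit missing state. Regional daily maxima are unweighted means over
reporting stations (no area or population weighting — the aggregation
contract is a plain average), with region-days lacking any report omitted
rather than imputed. Monthly values average the available daily values and
report coverage. Malformed CSV rows are rejected with their row numbers
logged, never silently dropped.

## Attention index

`index = n_posts / gdp` with GDP per capita in ten-thousand-yuan units.
Zero-post region-days are retained as index 0 by default: they are
informative about the cold limb of the attention curve (a `drop_zero_days`
flag inverts this, applied consistently through the perception fit). The
index is validated by Spearman rank correlation (average ranks for ties,
two-sided p from the large-sample t approximation, via scipy) between
period attention and period-mean daily maximum temperature; the pairing
against period-mean tmax is a documented choice, and p-values are reported
but never used for gating.

## Perception model

Per region, daily attention is regressed on (1, ω, ω²) by ordinary least
squares — no weighting or robust loss. Preconditions: ≥3 distinct
temperatures and a full-rank design. Derived statistics:

- vertex −a1/(2a2), defined only for a2 > 0 ("non-convex" flag otherwise);
- sensitivity = a2 verbatim;
- tolerance = larger root of a2ω² + a1ω + (a0 − M) = 0 where M is the
  arithmetic mean of the region's daily attention over the study window
  (zero-days included consistently with the attention flag); undefined
  with a "no-intersection" flag when the discriminant is negative;
- perception threshold = post-weighted mean daily maximum over posting
  days (each post contributes its day's temperature once; averaging over
  posts rather than posting days is a declared convention).

Undefined values are flagged, not raised, so national tables degrade
gracefully when some regions fit non-convex at 62 points.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable with known ground truth:

- **Temperatures**: per station, ω_t = mean + amplitude·sin(2π·doy/365) +
  AR(1) residual with Gaussian innovations (stationary initialisation),
  emitted in °F through the GSOD dialect so the reader path is exercised.
  Defaults: mean 29 °C, amplitude 3 °C, AR(1) 0.6, innovation sd 1.5 °C —
  a plausible peak-summer regime.
- **Post counts**: per region-day, Poisson with rate
  λ = gdp·max(a0 + a1ω + a2ω², floor). Counts are nonnegative integers and
  the additive noise of the regression model is otherwise unspecified;
  Poisson makes the attention index an unbiased estimate of the generative
  quadratic. The rate floor (default 0.1) keeps λ positive where a
  quadratic would go negative; it is configurable, and the Poisson choice
  itself is a stand-in one could swap.
- **Texts**: the standard LDA generative process over an abstract
  vocabulary (θ ~ Dir(0.1), document lengths Poisson with mean 12,
  truncated at 1). Four heat-keyword tokens carry 10% of every topic's
  mass, so keyword filtering — how a real corpus is collected — thins
  posts by a region-independent factor and leaves vertex and tolerance
  estimates unchanged (sensitivity scales by the retention rate, rank
  order preserved).
- **Reference conditions** (`default_world`): 10 regions, 62-day
  July–August window, generative vertices spanning 24–34 °C, curvatures
  0.1–1.0 (the span seen across real provinces), per-capita GDP 3–13
  ten-thousand-yuan; this emits ~7×10⁴ posts, the order of a real
  peak-summer crawl.

Randomness: one seed per world; per-region and per-station substreams are
derived with `SeedSequence` spawn keys, so a region's draws are invariant
to unrelated config edits. Same seed ⇒ byte-identical serialized worlds.

What the generator does *not* emulate: real Chinese text (the vocabulary
is abstract tokens), user demographics, reposting/censorship dynamics,
platform-penetration differences beyond the GDP proxy, humidity effects,
and spatially correlated weather across regions. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to the full messiness of real social-media
data.

## Numerical choices

- Quadratic fits use `numpy.linalg.lstsq`; rank < 3 raises (collinear
  design). r² is 1 − SS_res/SS_tot, defined as 1 for constant responses.
- Tolerance uses the closed-form root; the discriminant test is strict
  (a tiny negative discriminant from rounding yields "no-intersection"
  rather than a fabricated root).
- Ranking tie-breaks are lexicographic everywhere (word frequencies, top
  words, platform markers) for deterministic outputs.
- The Gibbs inner loop runs over plain Python ints for the small K used
  here; counts are re-materialised as numpy arrays afterwards and the
  conservation invariants asserted.
- The collapsed log joint is computed with `scipy.special.gammaln` from
  the count tables.

## Problem sizes

The test suite and the acceptance script use deliberately desk-scale
sizes, chosen so the full suite runs in about a minute: enumeration
oracles on ≤12-token corpora (4096 assignments at K=2), topic recovery at
500–5000 documents, perception recovery on the 10-region reference world,
noise studies at 200 replicates. These sizes were chosen as the smallest
at which the Monte-Carlo bands in the assertions are meaningful.

## Known limitations

- Dominant-topic assignment by argmax discards mixture information; shares
  are sensitive to K misspecification (K is a flag, default 4).
- The attention index inherits the GDP proxy's blind spots (populations
  with limited digital access are under-represented by construction).
- With only ~60 observations per region, low-curvature regions can fit
  non-convex at some seeds; their tolerance is then undefined by contract
  and excluded from rank-correlation summaries (the `n` field reports how
  many regions entered).
- No humidity or heat-index computation; temperature is daily maximum °C
  throughout.
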