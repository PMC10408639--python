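# Methods

## Problem setting

Public opinions about palliative and end-of-life care (PEoLC) during a
health emergency are visible in social-media text, but PEoLC posts are a
tiny fraction of the overall stream. The pipeline isolates that
fraction with a curated keyword filter, localizes it geographically and
temporally, and extracts discussion topics without supervised labels.
Topics are operationalized as communities in a term co-occurrence
network rather than as mixture components (LDA-style models degrade on
very short documents); the communities are handed to a human for
interpretation — the package never auto-labels topics, because naming a
cluster of keywords is an interpretive act.

## Corpus construction

**Keyword filter.** The bundled PEoLC term list (59 unique strings) is
matched as case-insensitive substrings of whitespace-collapsed text.
Substring rather than token-boundary matching is deliberate: the list
mixes hashtags ("#hpm"), fused forms ("pallcare", "eolc") and multiword
phrases ("end of life care"), and substring semantics covers all three
uniformly. The cost is potential over-matching (a term embedded in a
longer word); the synthetic generator's vocabularies are constructed to
avoid such collisions so the filter is exact on generated corpora.

**Geocoding.** Profile locations are free text, so resolution uses a
small auditable gazetteer: country names and abbreviations, US states
(names and postal codes), Canadian provinces, UK nations, and ~70 major
cities. The longest phrase wins locally; a string resolves only when
all its hits agree on one country, otherwise `None` ("London / New
York" resolves to nothing). Two-letter tokens are matched only in
uppercase, and US state codes take precedence over clashing ISO country
codes, so "Los Angeles, CA" is Californian rather than ambiguous with
Canada, at the cost of never resolving a bare "CA" to Canada.

**Period split.** Each country's corpus splits at 00:00 UTC on its
vaccination-program start date; the start day itself counts as "post",
reading "after the start" inclusively. Pre + post always partitions the
country's records exactly. Reported shares use half-up decimal rounding
(`share()`), matching how such percentages are conventionally printed;
the Canadian shares print at 0 decimals, the rest at 2.

Retweets and duplicate texts are retained by default; `dedupe_texts`
(CLI `--dedupe`) optionally drops exact text duplicates, keeping the
earliest.

## Preprocessing

Four steps in fixed order: clean → tokenize → stopword removal →
normalization.

- Cleaning removes URLs (`http(s)://…`, `www.…`, `t.co/…`) and emoji
  (explicit Unicode emoji-block ranges — pictographs, emoticons,
  transport, flags, dingbats, variation selectors — rather than a
  hand list of glyphs). Mentions lose their `@` and hashtags their
  `#` with the body kept, since hashtag bodies ("hpm", "hapc") carry
  topical vocabulary in this domain.
- Tokenization lowercases and splits on non-word characters, dropping
  tokens shorter than 2 characters and purely numeric tokens (both
  configurable). These two drops are quality choices to keep the
  co-occurrence vocabulary meaningful; "covid19" survives.
- The default stopword list is scikit-learn's English list, which
  includes the canonical examples ("i", "this", "with", "or"); any
  plain-text list can be substituted.
- Normalization defaults to a noun-default dictionary/rule lemmatizer
  (regular plural stripping plus an irregular-noun exception table;
  verb forms pass through, so "died" stays "died"). Lemmatization is
  the canonical normalizer because reported topic keywords are lemmas
  ("vaccine", "family"), not stems; a light suffix-stripping stemmer
  and identity are available via `normalizer=`. A lemma that lands on
  a stopword ("ones" → "one") is filtered after normalization, which
  also makes the full chain idempotent.

## PMI co-occurrence network

Occurrence is binary per tweet: a term repeated within one tweet counts
once, and `P(w) = df(w)/n`, `P(w1w2) = codf(w1,w2)/n` over the n
filtered tweets. Edges are weighted
`PMI = ln(codf·n / (df1·df2))`; natural log, unsmoothed. The base is
behavior-neutral downstream — modularity normalizes by total weight, so
a change of base rescales every A_ij, k_i and m by the same constant.

Vocabulary selection keeps the `top_n` terms by document frequency
(default 150, ties lexicographic); edges require a co-document count of
at least `min_co` (default 2) **and** PMI > 0. Non-positive-PMI pairs
are dropped because PMI exists here precisely to correct frequency-only
weighting, and modularity over negative weights is ill-defined. The
defaults comfortably exceed the ~75-node floor below which
co-occurrence analysis is considered unreliable at corpus sizes of a
few hundred to a few thousand tweets; a warning fires when a network
comes out smaller. Window = whole tweet (no sliding window):
tweet-length documents make the document itself the natural
co-occurrence unit.

## Modularity and Louvain

Modularity is evaluated over ordered pairs including i = j (A_ii = 0 at
the term level, but the null-model term k_i²/2m still enters the
diagonal). The implementation aggregates per community
(`Q = Σ_c [W_in(c)/2m − (tot_c/2m)²]`); the test suite checks it to
1e-12 against a naive double loop and against networkx.

Louvain phase 1 starts from singleton communities and sweeps nodes in a
seed-shuffled canonical (sorted) order, moving each node to the
neighboring community with maximal positive modularity gain; ties break
toward the smallest community id, making runs reproducible. Sweeps
repeat until no move gains more than `tolerance` (default 1e-12 — the
stopping rule is "no improvement", and 1e-12 distinguishes genuine
gains from floating-point noise). Phase 2 aggregates communities into
super-nodes with self-loop weight 2× the internal weight (so degrees
and m are conserved) and repeats; a level with no improvement
terminates. Accepted moves strictly increase Q, so Q is monotone and
the final Q is at least the singleton partition's.

Because visiting order derives from sorted node labels before the
seeded shuffle, relabeling equivariance holds exactly for
order-preserving renamings; an arbitrary renaming can change the visit
path and, on degenerate ties, the local optimum reached. On all
exhaustively solvable fixtures (≤ 8 nodes, Bell-number enumeration)
Louvain attains the global maximum-modularity partition.

## Topic reports

Keywords rank by within-community weighted degree (sum of PMI weights
to same-community neighbors, ties lexicographic); raw document
frequency is available as an alternative. Representative documents are
those covering the most of a topic's top-10 keywords, ties to the
earlier timestamp. Pre/post comparison greedily matches communities by
Jaccard similarity of their top-20 keyword sets; communities whose best
match falls below 0.1 are reported as emergent (post-only) or vanished
(pre-only). The 0.1 default operationalizes "a topic with essentially
no counterpart in the other period" and is configurable.

## Synthetic corpora

The generator emulates the corpus regime the pipeline targets: short
documents (8–20 tokens by default), K latent topics realized as
Dirichlet-weighted term distributions with a controllable shared-vocabulary
fraction (`overlap`), one verbatim filter term inserted with probability
`peolc_fraction`, gazetteer-resolvable locations for US/GB/CA, and
uniform timestamps across Oct 2020 – Mar 2021 around a changepoint.
Topic assignment is single-topic per tweet, matching the hard community
assignment the pipeline outputs and making purity well defined.
Generated terms are pseudo-words (CV syllables from a reduced alphabet)
that are rejected if they collide, as substrings in either direction,
with any filter term — so filter recall is exact by construction. A
`noise_fraction` of tweets (default 0.1) additionally receives a URL,
an emoji and a stopword to exercise the cleaning stages.

What the generator does **not** model: realistic language (Zipfian
vocabulary, grammar), user networks, retweet dynamics, hashtag
conventions, topic mixtures within a tweet, or class imbalance between
topics. Passing recovery tests therefore shows the pipeline is correct
and well calibrated on separable planted structure; it does not certify
recovery quality on real, messier streams, where topic boundaries are
softer and vocabulary overlap much higher.

Test and acceptance problem sizes — corpora of 1200–1500 tweets with
~30% filter-positive, 80-term networks, five seeds — were chosen as the
smallest sizes at which every stage operates in its intended regime
(several hundred filtered documents per network, comfortably above the
minimum viable network size for the reduced vocabulary).

## Numerical and degenerate-input choices

- PMI of a never-co-occurring pair is −∞ (sentinel; such edges are
  never retained). Terms absent from the statistics raise `KeyError`.
- Empty corpora, edgeless networks and empty stopword lists raise
  informative errors rather than returning degenerate objects.
- An all-in-one-community partition scores Q = 0 algebraically; a
  single unit edge with singleton communities scores −0.5 (the lower
  bound of the Q range).
- Percentages use `decimal.Decimal` half-up quantization, not binary
  float rounding.

## Known limitations

- The gazetteer is intentionally small; profile strings outside its
  coverage (neighborhoods, jokes, emoji-only) resolve to `None` and are
  excluded from country-level analyses, mirroring the unavoidable loss
  when only ~73% of filtered tweets carry usable location text.
- The keyword filter has no recall guarantee on real text: PEoLC
  discussion that avoids every listed term is invisible to the
  pipeline.
- Louvain is a heuristic: on large graphs it may return a
  partition below the (intractable) global optimum, and results depend
  on the seed; the default seed 0 is documented and fixed for
  reproducibility.
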