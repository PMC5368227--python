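# Methods

## Matching model

Primers and templates are IUPAC nucleotide strings; each code denotes a
subset of {A,C,G,T} (U folds onto T at ingest; everything is stored
uppercase). A template position matches a primer position iff the
template's base set is **contained** in the primer's. Consequences: a
concrete template base matches iff the primer accepts it; template N
matches only primer N. This containment rule is conservative — an
ambiguous database base is counted as a mismatch unless the primer is
guaranteed to bind every base it could be — and keeps all downstream
statistics deterministic. Ambiguity codes are rare in curated rRNA
references, so the choice has negligible numerical effect.

## Binding-site search

For one primer and one template the search considers semi-global
alignments: the primer aligned end-to-end, the template free at both
ends, with at most `max_gaps` indels (default 2). Template insertions
are only meaningful strictly inside the primer span (an end insertion
is the same thing as shifting the site) and the 3′-terminal primer base
must always be aligned to a template base — an indel is never allowed
to absorb it. Without that rule a terminal-base deletion (penalty 3.00)
would always undercut a terminal-base mismatch (1.00 + 3.00), the
terminal penalty could never fire, and last-base mismatch percentages
would be structurally zero. Reverse-orientation primers are scanned
against the reverse complement of the template and site coordinates
are mapped back to the plus strand (1-based, inclusive).

The site is chosen by a lexicographic objective: minimise the **unit
cost** (mismatches + gaps) first, break ties by lower weighted score,
then by position — nearest the primer's *E. coli* coordinates when the
template looks full-length (≥ 1,200 nt), else leftmost. Both the
weighted and the tp score are then computed on that single alignment.

Localization must not minimise the weighted score directly. Non-3′
mismatches cost 0.40, so the minimum ungapped weighted score of a
17-mer over a ~1.4-kb random (or off-target) sequence averages about
2.8; a genuine binding site carrying one terminal mismatch (4.00) would
lose to background noise, the reported hit would wander off-locus, and
terminal-base statistics and tp coverage would be corrupted. Unit cost
separates cleanly: genuine sites carry 0–2 defects while random
windows mismatch at roughly three quarters of positions.

Implementation: a vectorised scan of every ungapped offset, then — only
when an indel could still improve the optimum, i.e. when the best
ungapped combined cost exceeds one gap's cost floor — a gap-budgeted
dynamic program over states (primer position, template position, gaps
used). Both stages optimise `unit × 1024 + weighted`; since any
weighted score is far below 1024 this encoding is exactly
lexicographic. Defect counts and the site's start coordinate come from
a deterministic traceback (transition preference: substitution,
deletion, insertion); final scores are recomputed from the counts via
the public formula and rounded to 9 decimals so that algebraically
equal scores are bit-equal regardless of summation order. A template
shorter than the primer yields a truncated non-hit whose scores are
+inf (serialised as null).

Gap-region classification: a deleted primer base belongs to the region
of its own position; an inserted template base between primer positions
j and j+1 belongs to the region of position j+1. The 3′ region is the
final `three_prime_len` bases (default 5, the community convention).

## Scoring parameters

| parameter | default | meaning |
|---|---|---|
| `w_non3p_mm` | 0.40 | penalty per mismatch outside the 3′ region |
| `w_3p_mm` | 1.00 | penalty per mismatch inside the 3′ region |
| `w_non3p_gap` | 1.00 | penalty per indel outside the 3′ region |
| `w_3p_gap` | 3.00 | penalty per indel inside the 3′ region |
| `terminal_penalty` | 3.00 | added when the final 3′ base mismatches |
| `three_prime_len` | 5 nt | size of the 3′ region |
| `hit_threshold` | 1.0 | max score still counted as amplifiable |
| `max_gaps` | 2 | indel budget of the site search |

The tp score is the unit count of all mismatches plus gaps, with no
positional weighting and no terminal penalty — the simplest consistent
definition of a "total primer mismatch" method — and shares the hit
threshold.

## Coverage semantics

A record is covered by a pair when both primers score ≤ threshold
(under the configured method), neither site is truncated, and the
forward site lies 5′ of the reverse site on the plus strand — joint
per-sequence success, not a product of marginal rates. Records that
cannot span a primer locus are excluded from denominators by default
(a fragment says nothing about primer binding on the full gene);
`count_truncated_as_miss` switches to the stricter policy, and
published full-database coverage percentages can depend on which policy
the original tool applied. Records lacking taxonomy at the requested
rank aggregate under `Unclassified`. Percentages are reported to 2
decimals in TSV and full precision in JSON.

## Amplicon prediction

At most one amplicon per record: the best site pair, spanning the
forward primer's 5′ end through the plus-strand image of the reverse
primer's 5′ end, both sites included. For 341f (341–357) and 785r
(785–805) on a full-length gene this is 465 nt including primers; note
that "expected amplicon size" figures computed as the difference of
primer name positions understate this span. Length histograms grouped
by taxon expose inter-site length polymorphisms, e.g. taxa carrying an
internal deletion produce a second mode offset by exactly the deletion
length — the mechanism behind dual amplicon peaks in mixed-template
sequencing runs.

## Synthetic reference sets

The generator emulates the structure that matters to primer
evaluation, nothing more: random A/C/G/T backgrounds of 16S-like
length (default 1,200–1,600 nt, raised when a planted primer's
coordinates require it), concrete realisations of each degenerate
primer written at the *E. coli* coordinates, and planted defects with
exact bookkeeping. Defects are assigned by deterministic quota — the
first ⌈fraction × n − 0.5⌉ records of a taxon by index (round half up)
— so expected per-taxon coverage under any scoring configuration is a
closed-form consequence of the config, and recovery tests demand exact
equality instead of statistical agreement. A `stochastic` switch
substitutes Bernoulli draws, with the manifest then recording realised
counts.

Two hygiene rules make planted terminal mismatches exactly
recoverable. First, backgrounds are rejection-sampled so no off-site
window (either strand) mismatches a planted primer at fewer than 4
positions; planted sites carry at most a couple of defects, so they are
always the unambiguous best hits. Second, a terminal mismatch must not
be re-alignable as a cheaper or equal-cost gap: the planted base at
primer position m−1 is realised outside the terminal base's accepted
set, and the template base just 3′ of the site is set to mismatch the
terminal base. For primers whose position-(m−1) set is contained in the
terminal set (a repeated final base, e.g. 785r …CC or 518r …GG) no such
realisation exists — a single-base deletion one position in from the 3′
end is then genuinely indistinguishable-or-better for the search — and
the generator raises a config error rather than emit a wrong manifest.

What the generator does **not** emulate: phylogenetically realistic
sequence evolution, conserved/variable region structure outside the
primer loci, database fragments (truncated records), chimeras, or
read-level error. Passing recovery tests therefore demonstrates that
the pipeline measures planted signal exactly; it does not validate
coverage numbers on real databases, where alignment-policy and
denominator-policy choices (above) matter.

## Problem sizes

Recovery and acceptance runs use 5 taxa × 50 records (coverage
recovery at planted rates 0/10/25/50/100%), 100 records for
amplicon-length bimodality (30% carrying a 21-nt deletion), 200
random primer/template pairs (primers ≤ 12 nt, templates ≤ 60 nt) for
exact agreement between the production search and a brute-force
alignment enumeration, and 10 seeds for the round-trip determinism
property. These sizes make every planted effect exactly recoverable
while keeping a full run in seconds.

## Known limitations

* One best site per primer per record; secondary/off-target sites are
  logged but not reported.
* The weighted/tp comparison applies both thresholds to the same
  (unit-cost-optimal) alignment rather than re-optimising per method;
  for defect patterns a real site produces these coincide.
* Exact terminal-mismatch planting is impossible for primers with a
  repeated 3′-terminal base (generator raises an error; see above).
* No thermodynamics: scores are positional mismatch/gap counts, not
  ΔG or melting temperature, and no amplification kinetics are
  modelled.
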