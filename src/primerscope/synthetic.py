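"""Synthetic taxonomy-annotated 16S-like reference sets with planted,
exactly-bookkept primer-site defects.

Each generated record is a random A/C/G/T background of 16S-like length
with concrete realisations of the primer pair's binding sites written at
their E. coli coordinates.  Defects — substitutions at chosen primer
positions (terminal or not), single-base gaps inside a site, and
internal deletions between the sites (emulating the Alphaproteobacteria
length polymorphism around E. coli positions 454-485) — are planted on a
deterministic quota: the first ``round(fraction * n)`` records of a
taxon, by index.  Because planting is deterministic, the per-taxon
coverage expected under any scoring configuration is computed in closed
form and shipped in a ground-truth manifest; pipeline recovery tests can
demand exact equality rather than statistical agreement.

A ``stochastic`` switch replaces quotas with Bernoulli draws for users
who want sampling noise; the manifest then records realised counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .iupac import IUPAC_BASES, reverse_complement
from .primers import Primer, default_primers
from .records import ReferenceRecord, write_reference_fasta, write_taxonomy_tsv
from .scoring import ScoringConfig, weighted_score, tp_score, _ungapped_scan
from .iupac import encode

__all__ = [
    "DefectSpec",
    "DeletionSpec",
    "TaxonSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_reference_set",
    "plant_defect",
    "write_synthetic_outputs",
]

#: Background windows with fewer mismatches than this against any planted
#: primer (either strand) cause a redraw, so planted sites — which carry at
#: most a couple of defects — are always the unambiguous best hits.
_REJECT_MIN_MISMATCHES = 4


@dataclass(frozen=True)
class DefectSpec:
    """One planted in-site defect applied to a fraction of a taxon."""

    primer: str  # "fwd" | "rev"
    type: str  # "mismatch" | "gap"
    primer_position: int  # 1-based along the primer, 5'->3'
    fraction: float
    pair_index: int = 0

    def __post_init__(self):
        if self.primer not in ("fwd", "rev"):
            raise ValueError("defect primer must be 'fwd' or 'rev'")
        if self.type not in ("mismatch", "gap"):
            raise ValueError("defect type must be 'mismatch' or 'gap'")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("defect fraction must be in [0, 1]")


@dataclass(frozen=True)
class DeletionSpec:
    """Internal deletion between the primer sites of a pair."""

    length: int
    fraction: float
    pair_index: int = 0


@dataclass
class TaxonSpec:
    """One taxon of the synthetic set: size and defect profile."""

    name: str  # semicolon path, e.g. "Bacteria;PhylumA"
    n_records: int
    defects: list[DefectSpec] = field(default_factory=list)
    deletion: DeletionSpec | None = None

    @property
    def taxonomy(self) -> tuple[str, ...]:
        return tuple(t.strip() for t in self.name.split(";") if t.strip())


@dataclass
class GeneratorConfig:
    taxa: list[TaxonSpec]
    pair_names: list[tuple[str, str]] = field(
        default_factory=lambda: [("341f", "785r")]
    )
    length_range: tuple[int, int] = (1200, 1600)
    deletion_at: int = 454  # E. coli position where internal deletions start
    stochastic: bool = False
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    primers: list[Primer] | None = None

    def resolve_pairs(self) -> list[tuple[Primer, Primer]]:
        by_name = {p.name: p for p in (self.primers or default_primers())}
        pairs = []
        for f, r in self.pair_names:
            try:
                pairs.append((by_name[f], by_name[r]))
            except KeyError as exc:
                raise ValueError(f"unknown primer name {exc.args[0]!r}") from None
        return pairs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_raw(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_yaml_text(cls, text: str) -> "GeneratorConfig":
        return cls.from_raw(yaml.safe_load(text))

    @classmethod
    def from_raw(cls, raw: dict) -> "GeneratorConfig":
        taxa = []
        for t in raw.get("taxa", []):
            defects = [DefectSpec(**d) for d in t.get("defects", [])]
            deletion = DeletionSpec(**t["deletion"]) if t.get("deletion") else None
            taxa.append(
                TaxonSpec(
                    name=t["name"],
                    n_records=int(t["n_records"]),
                    defects=defects,
                    deletion=deletion,
                )
            )
        kwargs: dict = {"taxa": taxa}
        if "pairs" in raw:
            kwargs["pair_names"] = [tuple(p) for p in raw["pairs"]]
        if "length_range" in raw:
            kwargs["length_range"] = tuple(raw["length_range"])
        for key in ("deletion_at", "stochastic"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated set: what was planted, what any
    scoring run must recover."""

    seed: int
    n_records: int
    pair_names: list[tuple[str, str]]
    taxa: dict  # taxon path -> per-taxon truth dict

    def expected_coverage(self, taxon: str, method: str = "weighted",
                          pair_index: int = 0) -> float:
        return self.taxa[taxon]["pairs"][pair_index][f"coverage_{method}_pct"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_records": self.n_records,
            "pair_names": [list(p) for p in self.pair_names],
            "taxa": self.taxa,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        raw["pair_names"] = [tuple(p) for p in raw["pair_names"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# planting primitives

_ACGT = "ACGT"


def _mismatch_base(primer: Primer, primer_position: int, template_is_rc: bool) -> str:
    """Deterministic template base that mismatches the primer position.

    For reverse primers the template shows the complement strand, so the
    forbidden set is the complement of the primer's base set.
    """
    m = len(primer)
    if not 1 <= primer_position <= m:
        raise ValueError(
            f"primer position {primer_position} outside 1..{m} for {primer.name}"
        )
    accepted = IUPAC_BASES[primer.sequence[primer_position - 1]]
    if template_is_rc:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        accepted = frozenset(comp[b] for b in accepted)
    candidates = [b for b in _ACGT if b not in accepted]
    if not candidates:
        raise ValueError(
            f"cannot plant mismatch against N at position {primer_position} "
            f"of {primer.name}"
        )
    return candidates[0]


def _site_template_index(primer: Primer, site_start0: int, primer_position: int) -> int:
    """0-based template index aligned to a primer position at a site."""
    m = len(primer)
    if primer.orientation == "reverse":
        return site_start0 + (m - primer_position)
    return site_start0 + primer_position - 1


def plant_defect(
    sequence: str,
    primer: Primer,
    defect: dict,
    site_start: int,
) -> str:
    """Introduce one defect into a known primer site of a sequence.

    ``defect`` has keys ``type`` ("mismatch" or "gap") and
    ``primer_position`` (1-based, 5'->3' along the primer; the final
    position is the terminal 3' base).  ``site_start`` is the 1-based
    plus-strand start of the site.  A mismatch substitutes the aligned
    template base with one outside the primer's accepted set
    (deterministic choice); a gap deletes the aligned template base.
    """
    pos = int(defect["primer_position"])
    idx = _site_template_index(primer, site_start - 1, pos)
    if defect["type"] == "mismatch":
        base = _mismatch_base(primer, pos, primer.orientation == "reverse")
        return sequence[:idx] + base + sequence[idx + 1 :]
    elif defect["type"] == "gap":
        return sequence[:idx] + sequence[idx + 1 :]
    raise ValueError(f"unknown defect type {defect['type']!r}")


# ---------------------------------------------------------------------------
# closed-form truth

def _defect_counts(primer: Primer, defects: list[DefectSpec], cfg: ScoringConfig):
    """(non3p_mm, 3p_mm, non3p_gap, 3p_gap, last_mm) of a defect list."""
    m = len(primer)
    n3mm = t3mm = n3g = t3g = 0
    last = False
    for d in defects:
        in_3p = d.primer_position > m - cfg.three_prime_len
        if d.type == "mismatch":
            if in_3p:
                t3mm += 1
            else:
                n3mm += 1
            if d.primer_position == m:
                last = True
        else:
            if in_3p:
                t3g += 1
            else:
                n3g += 1
    return n3mm, t3mm, n3g, t3g, last


def planted_scores(primer: Primer, defects: list[DefectSpec],
                   cfg: ScoringConfig) -> tuple[float, float]:
    """(weighted, tp) score a planted defect list produces on re-scoring."""
    n3mm, t3mm, n3g, t3g, last = _defect_counts(primer, defects, cfg)
    return (
        weighted_score(n3mm, t3mm, n3g, t3g, last, cfg),
        tp_score(n3mm + t3mm, n3g + t3g),
    )


def _quota(fraction: float, n: int) -> int:
    # round half up so a 0.5-record quota is planted rather than dropped
    return int(fraction * n + 0.5)


# ---------------------------------------------------------------------------
# generation

def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _realise(rng: np.random.Generator, primer: Primer,
             evasion_proof_terminal: bool = False) -> str:
    """A concrete (A/C/G/T) realisation of a degenerate primer.

    When a terminal mismatch will be planted against this site, the base
    at position m-1 is drawn outside position m's accepted set so the
    site search cannot re-align the terminal base onto it (deleting
    position m-1) and dodge the terminal penalty.  Impossible for
    primers whose position-(m-1) set is contained in the terminal set
    (e.g. a repeated final base) — a config error.
    """
    bases = [
        sorted(IUPAC_BASES[c])[rng.integers(0, len(IUPAC_BASES[c]))]
        for c in primer.sequence
    ]
    if evasion_proof_terminal and len(primer) >= 2:
        m = len(primer)
        allowed = sorted(IUPAC_BASES[primer.sequence[m - 2]] - IUPAC_BASES[primer.sequence[m - 1]])
        if not allowed:
            raise ValueError(
                f"cannot plant an exact terminal mismatch against {primer.name}: "
                f"position {m-1} ({primer.sequence[m-2]}) cannot be realised "
                f"outside the terminal base set ({primer.sequence[m-1]})"
            )
        bases[m - 2] = allowed[rng.integers(0, len(allowed))]
    return "".join(bases)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _terminal_guard(seq: str, primer: Primer, site_start: int) -> str:
    """Set the template base just 3' of a site to mismatch the terminal
    primer base, blocking insertion-based evasion of the terminal penalty."""
    m = len(primer)
    term_set = IUPAC_BASES[primer.sequence[m - 1]]
    if primer.orientation == "reverse":
        idx = site_start - 2  # plus-strand base before the site
        choices = [b for b in _ACGT if _COMP[b] not in term_set]
    else:
        idx = site_start - 1 + m  # plus-strand base after the site
        choices = [b for b in _ACGT if b not in term_set]
    if not choices:
        raise ValueError(
            f"cannot guard terminal mismatch against N at 3' end of {primer.name}"
        )
    if not 0 <= idx < len(seq):
        return seq
    return seq[:idx] + choices[0] + seq[idx + 1 :]


def _has_offsite_nearmatch(seq: str, primers, cfg: ScoringConfig) -> bool:
    """Does any window mismatch suspiciously few bases of a planted primer?

    Checked on the pristine background, before sites are written, so any
    rejected window is accidental.
    """
    tenc = encode(seq)
    for p in primers:
        for scan in (p.sequence, reverse_complement(p.sequence)):
            penc = encode(scan, context="primer")
            if len(tenc) < len(penc):
                continue
            _, counts = _ungapped_scan(penc, tenc, cfg)
            if int(counts.min()) < _REJECT_MIN_MISMATCHES:
                return True
    return False


def _record_defects(spec: TaxonSpec, i: int, n: int, stochastic: bool,
                    rng: np.random.Generator):
    """Defects and deletion applied to record i of a taxon."""
    applied: list[DefectSpec] = []
    for d in spec.defects:
        hit = (rng.random() < d.fraction) if stochastic else i < _quota(d.fraction, n)
        if hit:
            applied.append(d)
    deletion = None
    if spec.deletion is not None:
        hit = (
            (rng.random() < spec.deletion.fraction)
            if stochastic
            else i < _quota(spec.deletion.fraction, n)
        )
        if hit:
            deletion = spec.deletion
    return applied, deletion


def generate_reference_set(
    config: GeneratorConfig, seed: int
) -> tuple[list[ReferenceRecord], SyntheticTruth]:
    """Generate a taxonomy-annotated reference set plus its ground truth.

    Deterministic for a fixed seed (identical records, byte-identical
    serialisations).  Raises a config error when a defect position falls
    outside its primer.
    """
    rng = np.random.default_rng(seed)
    pairs = config.resolve_pairs()
    all_primers = [p for pair in pairs for p in pair]
    lo, hi = config.length_range
    min_len = max(p.ecoli_end for p in all_primers) + 20
    lo = max(lo, min_len)
    hi = max(hi, lo)

    # validate defect positions up front
    for spec in config.taxa:
        for d in spec.defects:
            primer = pairs[d.pair_index][0 if d.primer == "fwd" else 1]
            if not 1 <= d.primer_position <= len(primer):
                raise ValueError(
                    f"taxon {spec.name}: defect position {d.primer_position} "
                    f"outside primer {primer.name} (length {len(primer)})"
                )
            if d.type == "mismatch":
                _mismatch_base(primer, d.primer_position, primer.orientation == "reverse")

    records: list[ReferenceRecord] = []
    taxa_truth: dict[str, dict] = {}
    counter = 0
    for spec in config.taxa:
        n = spec.n_records
        per_pair_amplifiable = {
            m: [0] * len(pairs) for m in ("weighted", "tp")
        }
        n_terminal = [0] * len(pairs)
        lengths: dict[int, dict[int, int]] = {k: {} for k in range(len(pairs))}
        for i in range(n):
            counter += 1
            rec_id = f"SYN{counter:06d}"
            applied, deletion = _record_defects(spec, i, n, config.stochastic, rng)

            length = int(rng.integers(lo, hi + 1))
            while True:
                bg = _random_background(rng, length)
                seq = "".join(_ACGT[b] for b in bg)
                if not _has_offsite_nearmatch(seq, all_primers, config.scoring):
                    break
            def has_terminal_mm(pair_idx, which, primer):
                return any(
                    d.pair_index == pair_idx and d.primer == which
                    and d.type == "mismatch" and d.primer_position == len(primer)
                    for d in applied
                )

            # write concrete primer sites at their E. coli coordinates
            site_starts: dict[tuple[int, str], int] = {}
            for k, (fwd, rev) in enumerate(pairs):
                fwd_site = _realise(rng, fwd, has_terminal_mm(k, "fwd", fwd))
                rev_site = reverse_complement(
                    _realise(rng, rev, has_terminal_mm(k, "rev", rev))
                )
                s_f, s_r = fwd.ecoli_start, rev.ecoli_start
                seq = seq[: s_f - 1] + fwd_site + seq[s_f - 1 + len(fwd) :]
                seq = seq[: s_r - 1] + rev_site + seq[s_r - 1 + len(rev) :]
                site_starts[(k, "fwd")] = s_f
                site_starts[(k, "rev")] = s_r
            # in-site defects (substitutions first, then single-base gaps;
            # gaps shift downstream coordinates so apply right-to-left)
            subs = [d for d in applied if d.type == "mismatch"]
            gaps = [d for d in applied if d.type == "gap"]
            for d in subs:
                primer = pairs[d.pair_index][0 if d.primer == "fwd" else 1]
                seq = plant_defect(
                    seq, primer, {"type": "mismatch", "primer_position": d.primer_position},
                    site_starts[(d.pair_index, d.primer)],
                )
                if d.primer_position == len(primer):
                    seq = _terminal_guard(seq, primer, site_starts[(d.pair_index, d.primer)])
            for d in sorted(
                gaps,
                key=lambda d: _site_template_index(
                    pairs[d.pair_index][0 if d.primer == "fwd" else 1],
                    site_starts[(d.pair_index, d.primer)] - 1,
                    d.primer_position,
                ),
                reverse=True,
            ):
                primer = pairs[d.pair_index][0 if d.primer == "fwd" else 1]
                seq = plant_defect(
                    seq, primer, {"type": "gap", "primer_position": d.primer_position},
                    site_starts[(d.pair_index, d.primer)],
                )
            # internal deletion between the pair's sites
            if deletion is not None:
                fwd, rev = pairs[deletion.pair_index]
                start0 = config.deletion_at - 1
                if not fwd.ecoli_end <= start0 + 1 <= rev.ecoli_start - deletion.length:
                    raise ValueError(
                        f"deletion at {config.deletion_at} (+{deletion.length} nt) "
                        f"does not fit between {fwd.name} and {rev.name} sites"
                    )
                seq = seq[:start0] + seq[start0 + deletion.length :]

            records.append(
                ReferenceRecord(id=rec_id, sequence=seq, taxonomy=spec.taxonomy)
            )

            # truth bookkeeping for this record
            for k, (fwd, rev) in enumerate(pairs):
                fdef = [d for d in applied if d.pair_index == k and d.primer == "fwd"]
                rdef = [d for d in applied if d.pair_index == k and d.primer == "rev"]
                fw, ft = planted_scores(fwd, fdef, config.scoring)
                rw, rt = planted_scores(rev, rdef, config.scoring)
                thr = config.scoring.hit_threshold
                cov_w = fw <= thr and rw <= thr
                cov_t = ft <= thr and rt <= thr
                if cov_w:
                    per_pair_amplifiable["weighted"][k] += 1
                if cov_t:
                    per_pair_amplifiable["tp"][k] += 1
                if any(
                    d.type == "mismatch" and d.primer_position == len(
                        fwd if d.primer == "fwd" else rev
                    )
                    for d in fdef + rdef
                ):
                    n_terminal[k] += 1
                amp_len = rev.ecoli_end - fwd.ecoli_start + 1
                if deletion is not None and deletion.pair_index == k:
                    amp_len -= deletion.length
                # in-site gaps inside the span also shift the length
                amp_len -= sum(
                    1 for d in applied if d.type == "gap" and d.pair_index == k
                )
                if cov_w or cov_t:
                    lengths[k][amp_len] = lengths[k].get(amp_len, 0) + 1

        taxa_truth[spec.name] = {
            "n_records": n,
            "pairs": [
                {
                    "pair": f"{pairs[k][0].name}/{pairs[k][1].name}",
                    "coverage_weighted_pct": 100.0
                    * per_pair_amplifiable["weighted"][k] / n,
                    "coverage_tp_pct": 100.0 * per_pair_amplifiable["tp"][k] / n,
                    "last_base_mm_pct": 100.0 * n_terminal[k] / n,
                    "amplicon_lengths": {
                        str(length): cnt for length, cnt in sorted(lengths[k].items())
                    },
                }
                for k in range(len(pairs))
            ],
        }

    truth = SyntheticTruth(
        seed=seed,
        n_records=len(records),
        pair_names=list(config.pair_names),
        taxa=taxa_truth,
    )
    return records, truth


def demo_config() -> GeneratorConfig:
    """A small demonstration set with two planted pairs.

    Defect rates are chosen so the broad-coverage pair 341f/785r beats
    68f/518r on every taxon (terminal-base mismatches against 68f in
    two phyla, and the Alphaproteobacteria-style 21-nt internal
    deletion that shortens the 341f/785r amplicon without affecting
    coverage).
    """
    return GeneratorConfig(
        taxa=[
            TaxonSpec(name="Bacteria;Proteobacteria;Alphaproteobacteria",
                      n_records=30,
                      deletion=DeletionSpec(length=21, fraction=1.0, pair_index=0)),
            TaxonSpec(name="Bacteria;Chlorobi", n_records=20, defects=[
                DefectSpec(primer="fwd", type="mismatch", primer_position=20,
                           fraction=0.4, pair_index=1),
            ]),
            TaxonSpec(name="Bacteria;Armatimonadetes", n_records=20, defects=[
                DefectSpec(primer="fwd", type="mismatch", primer_position=17,
                           fraction=0.2, pair_index=0),
                DefectSpec(primer="fwd", type="mismatch", primer_position=20,
                           fraction=0.6, pair_index=1),
            ]),
            TaxonSpec(name="Bacteria;Firmicutes", n_records=30, defects=[
                # two mismatches (3' 1.0 + non-3' 0.4) push 518r past threshold
                DefectSpec(primer="rev", type="mismatch", primer_position=16,
                           fraction=0.25, pair_index=1),
                DefectSpec(primer="rev", type="mismatch", primer_position=3,
                           fraction=0.25, pair_index=1),
            ]),
        ],
        pair_names=[("341f", "785r"), ("68f", "518r")],
    )


def write_synthetic_outputs(
    records: list[ReferenceRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + taxonomy TSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "taxonomy": outdir / f"{prefix}.taxonomy.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_reference_fasta(records, paths["fasta"])
    write_taxonomy_tsv(records, paths["taxonomy"])
    truth.to_json(paths["truth"])
    return paths
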