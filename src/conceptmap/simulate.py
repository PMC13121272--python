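"""Synthetic multi-site hospital coding corpora with ground-truth mappings.

Real NHS laboratory feeds are dominated by a handful of pathologies: heavy
abbreviation ("haemoglobin" recorded as "hb"), panel prefixes ("fbc fbc
hb"), local code suffixes ("U SODIUM_RAND_363_61"), shuffled word order,
and punctuation noise — with the vast majority of names unique to a single
hospital and concept frequencies following a Zipf law.  The generator
emulates those pathologies at desk scale: target names come from a seeded
grammar of analyte + property + specimen phrases, each target spawns a
geometric number of corrupted site-local variants, and a configurable
fraction of junk (administrative/storage) names with no legitimate target
is mixed in.

Each site draws its own abbreviation table, panel tokens and code-suffix
format; only a configurable fraction of abbreviation choices is shared
across sites, which is precisely what makes leave-one-site-out evaluation
land between the untrained baseline and the all-data fine-tuned model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    Domain,
    MappingRecord,
    MappingStatus,
    SourceConcept,
    TargetConcept,
    Vocabulary,
)
from .normalize import normalize_name

__all__ = [
    "SyntheticConfig",
    "SiteStyle",
    "SyntheticCorpus",
    "CORRUPTION_OPERATORS",
    "generate_vocabulary",
    "corrupt",
    "generate_corpus",
    "write_corpus",
]

# -- grammar ------------------------------------------------------------------

ANALYTES = [
    "haemoglobin", "sodium", "potassium", "creatinine", "urea", "glucose",
    "calcium", "magnesium", "phosphate", "albumin", "bilirubin", "cholesterol",
    "triglyceride", "ferritin", "transferrin", "folate", "cobalamin",
    "thyrotropin", "thyroxine", "cortisol", "prolactin", "testosterone",
    "oestradiol", "fibrinogen", "prothrombin", "lymphocyte", "neutrophil",
    "monocyte", "eosinophil", "basophil", "platelet", "erythrocyte",
    "reticulocyte", "haematocrit", "lactate", "ammonia", "amylase", "lipase",
    "troponin", "myoglobin", "urate", "chloride", "bicarbonate", "osmolality",
    "alanine aminotransferase", "aspartate aminotransferase",
    "alkaline phosphatase", "gamma glutamyl transferase", "lactate dehydrogenase",
    "c reactive protein", "immunoglobulin", "paraprotein", "aldosterone",
    "renin", "parathormone", "oestrone", "insulin", "glucagon", "gastrin",
    "caeruloplasmin", "haptoglobin", "myeloperoxidase", "procalcitonin",
    "homocysteine", "methotrexate", "vancomycin", "gentamicin", "digoxin",
    "lithium", "carbamazepine", "phenytoin",
]

PROPERTIES = [
    "substance concentration", "mass concentration", "count",
    "volume fraction", "arbitrary concentration", "catalytic activity",
    "molar ratio", "presence",
]

SPECIMENS = [
    "in serum", "in blood", "in plasma", "in urine",
    "in cerebrospinal fluid", "in faeces",
]

# common real-world short forms; sites pick one variant (or invent their own)
CANONICAL_ABBREVIATIONS = {
    "haemoglobin": ["hb", "hgb"],
    "sodium": ["na", "sod"],
    "potassium": ["k", "pot"],
    "creatinine": ["crea", "creat", "cr"],
    "urea": ["ur"],
    "glucose": ["glu", "gluc"],
    "calcium": ["ca", "cal"],
    "magnesium": ["mg", "mag"],
    "phosphate": ["po4", "phos"],
    "albumin": ["alb"],
    "bilirubin": ["bili", "tbil"],
    "cholesterol": ["chol"],
    "triglyceride": ["trig", "tg"],
    "ferritin": ["fer", "ferr"],
    "thyrotropin": ["tsh"],
    "thyroxine": ["t4", "ft4"],
    "fibrinogen": ["fib"],
    "prothrombin": ["pt"],
    "lymphocyte": ["lymph", "ly"],
    "neutrophil": ["neut", "ne"],
    "monocyte": ["mono"],
    "eosinophil": ["eos"],
    "basophil": ["baso"],
    "platelet": ["plt", "plts"],
    "erythrocyte": ["rbc"],
    "reticulocyte": ["retic"],
    "haematocrit": ["hct"],
    "alanine aminotransferase": ["alt"],
    "aspartate aminotransferase": ["ast"],
    "alkaline phosphatase": ["alp", "alk phos"],
    "gamma glutamyl transferase": ["ggt"],
    "lactate dehydrogenase": ["ldh"],
    "c reactive protein": ["crp"],
    "bicarbonate": ["hco3", "bicarb"],
    "chloride": ["cl"],
    "urate": ["ua"],
    "troponin": ["trop"],
}

PANEL_TOKENS = [
    "fbc", "ue", "lft", "bone", "coag", "tft", "chem", "glc", "lipid",
    "hitl", "rand", "prof", "screen",
]

JUNK_TOKENS = [
    "sample", "stored", "stor", "add", "on", "request", "comment", "label",
    "aliquot", "storage", "misc", "admin", "audit", "do", "not", "use",
    "see", "note", "test", "cancelled", "duplicate", "pending", "review",
]

CORRUPTION_OPERATORS = (
    "abbreviate",
    "panel_prefix",
    "code_suffix",
    "token_shuffle",
    "punctuation_noise",
)

# fixed audit timestamp for generated gold records (byte-identical reruns)
_SYNTH_TIMESTAMP = datetime(2025, 1, 1)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one synthetic corpus.

    Defaults are desk-scale: 200 targets across 5 sites, a geometric number
    of variants per target (mean 4, capped at 20), corruption operators
    weighted toward abbreviation and code suffixes, Zipf(1.2) concept
    frequencies, 99% of source names confined to one site, and 15% junk
    names with no legitimate target.
    """

    n_targets: int = 200
    n_sites: int = 5
    variants_mean: float = 4.0
    variants_max: int = 20
    corruption_weights: tuple[float, ...] = (0.35, 0.15, 0.25, 0.15, 0.10)
    zipf_exponent: float = 1.2
    site_uniqueness: float = 0.99
    not_relevant_rate: float = 0.15
    style_share: float = 0.35
    detail_drop: float = 0.70
    alias_rate: float = 0.60
    site_concentration: float = 0.70
    seed: int = 7
    domain: Domain = Domain.LAB_TEST
    vocabulary_id: str = "SYNTH-LAB"

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_sites < 1:
            raise ValueError("n_targets and n_sites must be positive")
        if abs(sum(self.corruption_weights) - 1.0) > 1e-9:
            raise ValueError("corruption weights must sum to 1")
        for name in (
            "site_uniqueness",
            "not_relevant_rate",
            "style_share",
            "detail_drop",
            "alias_rate",
            "site_concentration",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.variants_mean < 1:
            raise ValueError("variants_mean must be >= 1")


@dataclass(frozen=True)
class SiteStyle:
    """Site-specific corruption conventions."""

    site_id: str
    abbreviations: dict[str, str]  # analyte phrase -> short form
    panel_tokens: tuple[str, ...]
    suffix_letters: str  # site code used inside code suffixes


@dataclass
class SyntheticCorpus:
    vocabulary: Vocabulary
    sources: list[SourceConcept]
    gold: list[MappingRecord]
    styles: dict[str, SiteStyle] = field(default_factory=dict)

    @property
    def mapped_gold(self) -> list[MappingRecord]:
        return [r for r in self.gold if r.status is MappingStatus.MAPPED]


def _fallback_abbreviation(analyte: str, rng: np.random.Generator) -> str:
    """Short form for analytes without a canonical entry: clipped prefix or
    consonant skeleton of the first word."""
    word = analyte.split()[0]
    if rng.random() < 0.5:
        return word[: int(rng.integers(2, 5))]
    skeleton = word[0] + "".join(ch for ch in word[1:] if ch not in "aeiou")
    return skeleton[:4]


def _make_styles(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, SiteStyle]:
    # shared choices: the fraction of analytes whose short form every site agrees on
    shared: dict[str, str] = {}
    for analyte in ANALYTES:
        options = CANONICAL_ABBREVIATIONS.get(analyte)
        if options and rng.random() < config.style_share:
            shared[analyte] = options[int(rng.integers(len(options)))]
    styles = {}
    for s in range(config.n_sites):
        site_id = f"site{s + 1}"
        abbrevs = {}
        for analyte in ANALYTES:
            if analyte in shared:
                abbrevs[analyte] = shared[analyte]
            else:
                options = CANONICAL_ABBREVIATIONS.get(analyte, [])
                pool = list(options) + [_fallback_abbreviation(analyte, rng)]
                abbrevs[analyte] = pool[int(rng.integers(len(pool)))]
        n_panels = int(rng.integers(3, 6))
        panels = tuple(
            rng.choice(PANEL_TOKENS, size=n_panels, replace=False).tolist()
        )
        letters = "".join(
            chr(ord("a") + int(rng.integers(26))) for _ in range(3)
        )
        styles[site_id] = SiteStyle(site_id, abbrevs, panels, letters)
    return styles


def generate_vocabulary(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[Vocabulary, dict[str, str]]:
    """Seeded grammar vocabulary; also returns concept_id -> analyte."""
    capacity = len(ANALYTES) * len(PROPERTIES) * len(SPECIMENS)
    if config.n_targets > capacity:
        raise ValueError(
            f"grammar capacity {capacity} cannot yield {config.n_targets} targets"
        )
    combo_idx = rng.choice(capacity, size=config.n_targets, replace=False)
    concepts = []
    analyte_of: dict[str, str] = {}
    for i, ci in enumerate(combo_idx):
        a, rest = divmod(int(ci), len(PROPERTIES) * len(SPECIMENS))
        p, sp = divmod(rest, len(SPECIMENS))
        name = f"{ANALYTES[a]} {PROPERTIES[p]} {SPECIMENS[sp]}"
        cid = f"T{i:05d}"
        concepts.append(TargetConcept(cid, name, config.vocabulary_id))
        analyte_of[cid] = ANALYTES[a]
    return Vocabulary(config.vocabulary_id, concepts), analyte_of


def corrupt(
    name: str, operator: str, style: SiteStyle, rng: np.random.Generator
) -> str:
    """Apply one corruption operator to a (normalized) concept name.

    Returns a *raw* source name: punctuation noise may introduce casing and
    underscores that normalization will strip back out.
    """
    tokens = name.split()
    if operator == "abbreviate":
        for analyte, short in style.abbreviations.items():
            a_tokens = analyte.split()
            for i in range(len(tokens) - len(a_tokens) + 1):
                if tokens[i : i + len(a_tokens)] == a_tokens:
                    return " ".join(tokens[:i] + [short] + tokens[i + len(a_tokens):])
        return name
    if operator == "panel_prefix":
        panel = style.panel_tokens[int(rng.integers(len(style.panel_tokens)))]
        prefix = [panel, panel] if rng.random() < 0.5 else [panel]
        return " ".join(prefix + tokens)
    if operator == "code_suffix":
        code = f"{int(rng.integers(100, 1000))}_{int(rng.integers(10, 100))}"
        if rng.random() < 0.5:
            code = f"{style.suffix_letters}_{code}"
        return f"{name}_{code}"
    if operator == "token_shuffle":
        if len(tokens) < 2:
            return name
        while True:
            perm = rng.permutation(len(tokens))
            if not np.array_equal(perm, np.arange(len(tokens))):
                return " ".join(tokens[i] for i in perm)
    if operator == "punctuation_noise":
        out = []
        for tok in tokens:
            r = rng.random()
            if r < 0.3:
                tok = tok.upper()
            elif r < 0.5:
                tok = tok.capitalize()
            out.append(tok)
        joiner = "_" if rng.random() < 0.5 else "  "
        return joiner.join(out)
    raise ValueError(f"unknown corruption operator {operator!r}")


def _truncated_geometric(
    mean: float, cap: int, rng: np.random.Generator
) -> int:
    draw = int(rng.geometric(1.0 / mean))
    return min(max(draw, 1), cap)


def _zipf_frequencies(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Frequencies proportional to rank^-exponent, assigned in a random
    order over targets, scaled so the most common concept has count 1000."""
    ranks = np.arange(1, n + 1, dtype=np.float64)
    freq = np.maximum(1, np.round(1000.0 * ranks ** (-exponent))).astype(int)
    perm = rng.permutation(n)
    return freq[np.argsort(perm)]  # random assignment of ranks to targets


def generate_corpus(config: SyntheticConfig = SyntheticConfig()) -> SyntheticCorpus:
    """Draw a complete corpus: vocabulary, corrupted sources, gold mappings."""
    rng = np.random.default_rng(config.seed)
    vocabulary, analyte_of = generate_vocabulary(config, rng)
    styles = _make_styles(config, rng)
    site_ids = list(styles)
    target_freq = _zipf_frequencies(len(vocabulary), config.zipf_exponent, rng)

    op_names = list(CORRUPTION_OPERATORS)
    weights = np.asarray(config.corruption_weights)

    # site-local alias codes ("creup", "xhcb"): one opaque token per
    # (site, target), reused by every variant of that target at the site —
    # the learnable signal that lets fine-tuning generalize to unseen
    # variants without helping the untrained model
    alias_codes: dict[tuple[str, str], str] = {}

    def alias_for(site: str, target: TargetConcept) -> str:
        key = (site, target.concept_id)
        code = alias_codes.get(key)
        if code is None:
            stem = analyte_of[target.concept_id].split()[0][:3]
            tail = "".join(chr(ord("a") + int(rng.integers(26))) for _ in range(2))
            code = stem + tail
            alias_codes[key] = code
        return code

    sources: list[SourceConcept] = []
    gold: list[MappingRecord] = []
    seen: set[tuple[str, str]] = set()

    def add_source(raw: str, site: str, freq: int, target: Optional[TargetConcept]):
        src = SourceConcept(raw, site, config.domain, freq)
        sources.append(src)
        if target is not None:
            gold.append(
                MappingRecord(
                    source=src,
                    status=MappingStatus.MAPPED,
                    target=target,
                    reviewer_id="synthetic-oracle",
                    timestamp=_SYNTH_TIMESTAMP,
                )
            )
        else:
            gold.append(
                MappingRecord(
                    source=src,
                    status=MappingStatus.NOT_RELEVANT,
                    reviewer_id="synthetic-oracle",
                    timestamp=_SYNTH_TIMESTAMP,
                )
            )

    for t_idx, target in enumerate(vocabulary):
        n_variants = _truncated_geometric(config.variants_mean, config.variants_max, rng)
        split = rng.dirichlet(np.ones(n_variants))
        analyte = analyte_of[target.concept_id]
        qualifier = target.normalized_name.split()[len(analyte.split())]
        # each target has a home site where most of its variants accrue,
        # mirroring how one hospital's feed piles up renamings of one test
        home_site = site_ids[int(rng.integers(len(site_ids)))]
        for v in range(n_variants):
            freq = max(1, int(round(target_freq[t_idx] * split[v])))
            if rng.random() < config.site_concentration:
                site = home_site
            else:
                site = site_ids[int(rng.integers(len(site_ids)))]
            style = styles[site]
            raw = None
            for _ in range(20):  # retry for (name, site) uniqueness
                # hospital feeds rarely spell out the full reference-set
                # phrase: most variants start from the bare analyte, some
                # keep one qualifying word ("plt count"), few the full name
                r = rng.random()
                if r < config.detail_drop:
                    base = analyte
                elif r < config.detail_drop + 0.15:
                    base = f"{analyte} {qualifier}"
                else:
                    base = target.normalized_name
                n_ops = min(int(rng.integers(1, 4)), int(np.count_nonzero(weights)))
                chosen = rng.choice(
                    len(op_names), size=n_ops, replace=False, p=weights
                )
                # canonical application order keeps token-level operators
                # ahead of punctuation noise
                candidate = base
                if rng.random() < config.alias_rate:
                    candidate = f"{candidate} {alias_for(site, target)}"
                for oi in sorted(chosen):
                    candidate = corrupt(candidate, op_names[oi], style, rng)
                if (candidate, site) not in seen and normalize_name(candidate):
                    raw = candidate
                    break
            if raw is None:
                raise RuntimeError(
                    "could not draw a distinct corrupted variant after 20 tries"
                )
            seen.add((raw, site))
            add_source(raw, site, freq, target)
            if rng.random() > config.site_uniqueness and len(site_ids) > 1:
                others = [s for s in site_ids if s != site]
                twin = others[int(rng.integers(len(others)))]
                if (raw, twin) not in seen:
                    seen.add((raw, twin))
                    add_source(raw, twin, max(1, freq // 2), target)

    n_real = len(sources)
    n_junk = int(round(config.not_relevant_rate / (1.0 - config.not_relevant_rate) * n_real)) if config.not_relevant_rate > 0 else 0
    for _ in range(n_junk):
        site = site_ids[int(rng.integers(len(site_ids)))]
        style = styles[site]
        for _ in range(20):
            k = int(rng.integers(2, 5))
            toks = rng.choice(JUNK_TOKENS, size=k, replace=False).tolist()
            raw = "_".join(t.upper() for t in toks)
            if rng.random() < 0.5:
                raw = f"{raw}_{int(rng.integers(100, 1000))}"
            if (raw, site) not in seen:
                break
        seen.add((raw, site))
        add_source(raw, site, int(rng.integers(1, 30)), None)

    order = sorted(
        range(len(sources)),
        key=lambda i: (-sources[i].frequency, sources[i].normalized_name),
    )
    sources = [sources[i] for i in order]
    gold = [gold[i] for i in order]
    return SyntheticCorpus(vocabulary=vocabulary, sources=sources, gold=gold, styles=styles)


def write_corpus(corpus: SyntheticCorpus, directory: str | Path) -> None:
    """Write vocabulary.csv, sources.csv and gold_mappings.csv."""
    from .io import export_mappings

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "concept_id": [c.concept_id for c in corpus.vocabulary],
            "concept_name": [c.name for c in corpus.vocabulary],
            "vocabulary_id": [c.vocabulary_id for c in corpus.vocabulary],
        }
    ).to_csv(directory / "vocabulary.csv", index=False)
    pd.DataFrame(
        {
            "raw_name": [s.raw_name for s in corpus.sources],
            "site_id": [s.site_id for s in corpus.sources],
            "domain": [s.domain.value for s in corpus.sources],
            "frequency": [s.frequency for s in corpus.sources],
        }
    ).to_csv(directory / "sources.csv", index=False)
    export_mappings(corpus.gold, directory / "gold_mappings.csv")
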