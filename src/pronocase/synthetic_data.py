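"""Synthetic cohorts and annotated token streams for pipeline testing.

The study transcripts this package targets are clinical interviews that are
not publicly deposited, so every pipeline stage is exercised against a
generator calibrated to the published cohort structure:

* 319 participants with ~12% suicidal-ideation prevalence;
* near-complete depression co-occurrence in the suicidal group
  (37/38 depressed among suicidal vs 83/281 among non-suicidal);
* group-conditional age, gender and lifetime-diagnosis margins;
* group-conditional linguistic-feature rates drawn from truncated-normal
  (at 0) distributions with the published per-group means/SDs;
* token streams carrying CTB POS tags and dependency relations, rendered
  from the template inventory of :mod:`pronocase.annotation` so that the
  extraction pipeline recovers each participant's configured rates.

Transcript rendering samples template sentences i.i.d. with probabilities
solved so the *expected* token composition equals the target rates; pro-drop
(omission of the subject pronoun, frequent in Chinese) is emulated by a
per-sentence drop probability, compensated in the mix so realized subjective
rates still match their targets.  Rates are drawn from truncated normals
rather than gammas to honor the mean/SD parameterization directly; for
features whose mean is within a standard deviation of zero the truncation
shifts the realized mean upward — a documented modelling consequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .annotation import TEMPLATE_INVENTORY, ParsedUtterance
from .corpus_io import (
    Gender, Labels, ParticipantRecord, Speaker, TranscriptTurn,
    derive_labels, write_metadata, write_transcript,
)
from .features import CASE_FEATURES, FEATURE_NAMES

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "GROUP_RATE_DEFAULTS",
    "generate_cohort",
    "draw_feature_rates",
    "generate_feature_matrix",
    "generate_transcript",
    "generate_dataset",
    "implied_crude_or",
]


class GenerationError(ValueError):
    """The requested configuration cannot be generated."""


#: published per-group feature-rate means/SDs (percent of tokens):
#: (non-suicidal mean, non-suicidal SD, suicidal mean, suicidal SD)
GROUP_RATE_DEFAULTS: Dict[str, Tuple[float, float, float, float]] = {
    "possessive_fpsp": (0.24, 0.29, 0.32, 0.26),
    "subjective_fpsp": (1.73, 1.23, 2.14, 1.27),
    "objective_fpsp": (0.15, 0.21, 0.30, 0.25),
    "dative_fpsp": (0.03, 0.08, 0.04, 0.07),
    "fppp": (0.02, 0.07, 0.03, 0.06),
    "verb": (20.49, 2.76, 21.50, 1.82),
    "preposition": (0.96, 0.63, 1.06, 0.48),
    "temporal_noun": (0.86, 0.65, 0.89, 0.56),
    "etcetera": (0.02, 0.07, 0.01, 0.03),
    "interjection": (4.64, 2.00, 3.62, 1.29),
    "passive_marker": (0.001, 0.007, 0.003, 0.02),
}

_GENERATED_FEATURES = tuple(GROUP_RATE_DEFAULTS)  # total_fpsp is derived


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_participants: int = 319
    prevalence: float = 38 / 319
    p_depression_given_suicidal: float = 37 / 38
    p_depression_given_non_suicidal: float = 83 / 281
    age_mean_suicidal: float = 50.95
    age_sd_suicidal: float = 15.24
    age_mean_non_suicidal: float = 53.46
    age_sd_non_suicidal: float = 11.16
    p_female_suicidal: float = 23 / 38
    p_female_non_suicidal: float = 159 / 281
    p_lifetime_suicidal: float = 34 / 38
    p_lifetime_non_suicidal: float = 159 / 281
    #: feature -> (mean, sd) per group; percentages of tokens
    rates_non_suicidal: tuple = tuple(
        (k, (v[0], v[1])) for k, v in GROUP_RATE_DEFAULTS.items()
    )
    rates_suicidal: tuple = tuple(
        (k, (v[2], v[3])) for k, v in GROUP_RATE_DEFAULTS.items()
    )
    tokens_min: int = 500
    tokens_max: int = 3000
    pro_drop: float = 0.3
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.prevalence, self.p_depression_given_suicidal,
            self.p_depression_given_non_suicidal, self.p_female_suicidal,
            self.p_female_non_suicidal, self.p_lifetime_suicidal,
            self.p_lifetime_non_suicidal, self.pro_drop,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GenerationError("probabilities must lie in [0, 1]")
        if self.n_participants < 2:
            raise GenerationError("need at least 2 participants")
        if not 0 < self.tokens_min <= self.tokens_max:
            raise GenerationError("invalid tokens-per-transcript range")
        for group in (self.rates_non_suicidal, self.rates_suicidal):
            for name, (mean, sd) in group:
                if mean < 0 or sd < 0:
                    raise GenerationError(f"negative rate parameter for {name}")

    def group_rates(self, suicidal: bool) -> Dict[str, Tuple[float, float]]:
        return dict(self.rates_suicidal if suicidal else self.rates_non_suicidal)

    def with_rates(self, non_suicidal: Dict[str, Tuple[float, float]] | None = None,
                   suicidal: Dict[str, Tuple[float, float]] | None = None,
                   **kwargs) -> "GeneratorConfig":
        """Copy with per-group rate overrides merged over the defaults."""
        ns = self.group_rates(False)
        s = self.group_rates(True)
        ns.update(non_suicidal or {})
        s.update(suicidal or {})
        return replace(
            self,
            rates_non_suicidal=tuple(ns.items()),
            rates_suicidal=tuple(s.items()),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _truncnorm(mean: float, sd: float, lo: float, hi: float = np.inf):
    # cached: simulation studies re-freeze the same handful of distributions
    if sd == 0:
        return None
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm(a, b, loc=mean, scale=sd)


def _group_truncnorm_draws(
    u: np.ndarray, mask: np.ndarray,
    params0: Tuple[float, float], params1: Tuple[float, float],
    lo: float, hi: float = np.inf,
) -> np.ndarray:
    """Inverse-CDF truncated-normal draws with group-dependent parameters."""
    out = np.empty(len(u))
    for grp_mask, (mean, sd) in ((~mask, params0), (mask, params1)):
        if not grp_mask.any():
            continue
        dist = _truncnorm(mean, sd, lo, hi)
        out[grp_mask] = dist.ppf(u[grp_mask]) if dist is not None else mean
    return out


def generate_cohort(
    cfg: GeneratorConfig | None = None, rng: np.random.Generator | None = None
) -> Tuple[List[ParticipantRecord], List[Labels]]:
    """Draw participant metadata whose derived labels realize the configured
    prevalence and depression co-occurrence exactly by construction."""
    cfg = cfg or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    suicidal = rng.random(n) < cfg.prevalence
    p_dep = np.where(suicidal, cfg.p_depression_given_suicidal,
                     cfg.p_depression_given_non_suicidal)
    depressed = rng.random(n) < p_dep
    # ratings chosen so derive_labels reproduces the intended labels
    hdrs = np.where(depressed, 8 + rng.poisson(6.0, n), rng.integers(0, 8, n))
    h11 = np.where(
        suicidal, rng.choice([2, 3, 4, 5], size=n, p=[0.5, 0.25, 0.15, 0.1]), 1
    )
    ages = _group_truncnorm_draws(
        rng.random(n), suicidal,
        (cfg.age_mean_non_suicidal, cfg.age_sd_non_suicidal),
        (cfg.age_mean_suicidal, cfg.age_sd_suicidal),
        18.0, 65.0,
    )
    ages = np.clip(np.round(ages), 18, 65).astype(int)
    p_female = np.where(suicidal, cfg.p_female_suicidal, cfg.p_female_non_suicidal)
    female = rng.random(n) < p_female
    p_life = np.where(suicidal, cfg.p_lifetime_suicidal, cfg.p_lifetime_non_suicidal)
    lifetime = rng.random(n) < p_life

    records, labels = [], []
    for i in range(n):
        record = ParticipantRecord(
            participant_id=f"P{i + 1:04d}",
            age=int(ages[i]),
            gender=Gender.FEMALE if female[i] else Gender.MALE,
            hdrs_total=int(hdrs[i]),
            h11=int(h11[i]),
            lifetime_affective=bool(lifetime[i]),
        )
        derived = derive_labels(record)
        assert derived == Labels(bool(depressed[i]), bool(suicidal[i]))
        records.append(record)
        labels.append(derived)
    return records, labels


def draw_feature_rates(
    cfg: GeneratorConfig, suicidal: bool, rng: np.random.Generator
) -> Dict[str, float]:
    """Draw one participant's target feature percentages from the
    group-conditional truncated-normal (at 0) distributions."""
    rates = {}
    for name, (mean, sd) in cfg.group_rates(suicidal).items():
        dist = _truncnorm(mean, sd, 0.0)
        rates[name] = float(dist.ppf(rng.random())) if dist else mean
    return rates


def generate_feature_matrix(
    cfg: GeneratorConfig | None = None, rng: np.random.Generator | None = None
) -> Tuple[List[ParticipantRecord], List[Labels], pd.DataFrame]:
    """Fast path: cohort plus per-participant feature rates without rendering
    token streams (used for large simulation studies; rendering adds only
    multinomial sampling noise on top of these rates)."""
    cfg = cfg or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    records, labels = generate_cohort(cfg, rng)
    n = len(records)
    suicidal = np.array([lab.suicidal_ideation for lab in labels])
    rates_ns, rates_s = cfg.group_rates(False), cfg.group_rates(True)
    columns = {}
    for name in _GENERATED_FEATURES:
        columns[name] = _group_truncnorm_draws(
            rng.random(n), suicidal, rates_ns[name], rates_s[name], 0.0
        )
    columns["total_fpsp"] = sum(columns[c] for c in CASE_FEATURES)
    columns["token_total"] = rng.integers(cfg.tokens_min, cfg.tokens_max + 1, n)
    frame = pd.DataFrame(columns, index=[r.participant_id for r in records])
    frame.index.name = "participant_id"
    return records, labels, frame[list(FEATURE_NAMES) + ["token_total"]]


# ---------------------------------------------------------------------------
# Token-stream rendering
# ---------------------------------------------------------------------------

# synthesis templates: feature -> (full sentence, dropped variant or None)
_FEATURE_TEMPLATES: Dict[str, Tuple[str, str | None]] = {
    "subjective_fpsp": ("我好攰", "好攰"),
    "objective_fpsp": ("佢憎我", None),
    "dative_fpsp": ("佢俾我機會", None),
    "possessive_fpsp": ("我嘅諗法", None),
    "fppp": ("我哋嘅屋企", None),
    "preposition": ("喺屋企", None),
    "temporal_noun": ("今日", None),
    "etcetera": ("蘋果等等", None),
    "interjection": ("唉", None),
    "passive_marker": ("佢被人鬧", None),
}
_VERB_TEMPLATE = "食飯"
_PAD_TEMPLATES = ("嘢", "好多嘢。")   # plain / punctuated
_PAD_PUNCT_SHARE = 0.2

_VERB_POS = {"VV", "VC", "VE", "VA"}


def _template_stats(key: str) -> Tuple[int, int]:
    """(token count, verb count) of an inventory sentence."""
    parse = TEMPLATE_INVENTORY[key]
    return len(parse), sum(1 for t in parse.tokens if t.pos in _VERB_POS)


def _solve_template_mix(
    target_rates: Dict[str, float], pro_drop: float
) -> Tuple[List[str], np.ndarray]:
    """Solve sentence-draw probabilities so the expected token composition of
    an i.i.d. template stream equals ``target_rates`` (percent of tokens).

    Raises :class:`GenerationError` when the combination is unreachable —
    e.g. a verb rate smaller than the verbs embedded in the pronoun
    templates, or rates so high that no padding share remains.
    """
    unknown = set(target_rates) - set(_GENERATED_FEATURES)
    if unknown:
        raise GenerationError(f"unknown feature(s) in target rates: {sorted(unknown)}")
    rates = {name: float(target_rates.get(name, 0.0)) for name in _GENERATED_FEATURES}
    if any(r < 0 for r in rates.values()):
        raise GenerationError("target rates must be >= 0")
    exclusive = sum(v for k, v in rates.items() if k != "verb")
    if exclusive + rates["verb"] > 100.0:
        raise GenerationError("target rates exceed 100% of tokens")

    # per-unit-expected-tokens draw intensities a_f = rate / e_f
    intensities: Dict[str, float] = {}
    token_load = 0.0   # expected tokens contributed per unit T
    verb_load = 0.0    # expected verbs contributed per unit T
    for name, (full, dropped) in _FEATURE_TEMPLATES.items():
        L_full, v_full = _template_stats(full)
        if dropped is not None:
            L_drop, v_drop = _template_stats(dropped)
            e = 1.0 - pro_drop            # feature token survives the drop?
            L = (1 - pro_drop) * L_full + pro_drop * L_drop
            v = (1 - pro_drop) * v_full + pro_drop * v_drop
        else:
            e, L, v = 1.0, float(L_full), float(v_full)
        a = rates[name] / 100.0 / e if e > 0 else 0.0
        intensities[name] = a
        token_load += a * L
        verb_load += a * v

    a_verb = rates["verb"] / 100.0 - verb_load
    if a_verb < -1e-12:
        raise GenerationError(
            "verb rate is below the verbs embedded in the pronoun templates; "
            "combination unreachable"
        )
    a_verb = max(a_verb, 0.0)
    pad_token_share = 1.0 - token_load - a_verb
    if pad_token_share < -1e-12:
        raise GenerationError("target rates leave no room for padding tokens")
    pad_token_share = max(pad_token_share, 0.0)
    L_pad = (1 - _PAD_PUNCT_SHARE) * 1 + _PAD_PUNCT_SHARE * 3
    a_pad = pad_token_share / L_pad

    names = list(_FEATURE_TEMPLATES) + ["verb", "pad"]
    a = np.array([intensities[n] for n in _FEATURE_TEMPLATES] + [a_verb, a_pad])
    total = a.sum()
    if total <= 0:
        raise GenerationError("degenerate template mix (all probabilities zero)")
    return names, a / total


def generate_transcript(
    target_rates: Dict[str, float],
    n_tokens: int,
    seed: int | np.random.Generator = 0,
    pro_drop: float = 0.3,
) -> List[ParsedUtterance]:
    """Render a parsed token stream of at least ``n_tokens`` tokens whose
    expected feature composition equals ``target_rates`` (percentages)."""
    if n_tokens <= 0:
        raise GenerationError("n_tokens must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names, probs = _solve_template_mix(target_rates, pro_drop)
    utterances: List[ParsedUtterance] = []
    tokens = 0
    while tokens < n_tokens:
        # draw template choices in blocks for speed
        block = rng.choice(len(names), size=256, p=probs)
        sub = rng.random(size=(256, 2))
        for choice, (u1, u2) in zip(block, sub):
            name = names[choice]
            if name == "pad":
                key = _PAD_TEMPLATES[1] if u1 < _PAD_PUNCT_SHARE else _PAD_TEMPLATES[0]
            elif name == "verb":
                key = _VERB_TEMPLATE
            else:
                full, dropped = _FEATURE_TEMPLATES[name]
                key = dropped if (dropped is not None and u2 < pro_drop) else full
            parse = TEMPLATE_INVENTORY[key]
            utterances.append(parse)
            tokens += len(parse)
            if tokens >= n_tokens:
                break
    return utterances


_INTERVIEWER_PROMPTS = (
    "上個禮拜你瞓得點呀?", "最近心情點呀?", "有冇咩想同我講?",
)
_SENTENCES_PER_TURN = 8


def _utterances_to_turns(
    utterances: Sequence[ParsedUtterance], rng: np.random.Generator
) -> List[TranscriptTurn]:
    """Pack sentences into participant turns, interleaving interviewer
    prompts (which the extraction pipeline filters out)."""
    turns: List[TranscriptTurn] = []
    for start in range(0, len(utterances), _SENTENCES_PER_TURN):
        chunk = utterances[start:start + _SENTENCES_PER_TURN]
        prompt = _INTERVIEWER_PROMPTS[int(rng.integers(len(_INTERVIEWER_PROMPTS)))]
        turns.append(TranscriptTurn(Speaker.INTERVIEWER, prompt))
        turns.append(TranscriptTurn(Speaker.PARTICIPANT,
                                    "".join(u.text for u in chunk)))
    return turns


def generate_dataset(
    cfg: GeneratorConfig | None = None, out_dir: str | Path = "corpus_out"
) -> Path:
    """Write a full synthetic dataset: ``corpus/`` of JSON-lines transcripts,
    ``metadata.csv``, ``true_rates.csv`` (the generator's per-participant
    targets) and ``manifest.json`` (seed + config echo)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    corpus_dir = out_dir / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    records, labels = generate_cohort(cfg, rng)
    true_rates = {}
    for record, lab in zip(records, labels):
        rates = draw_feature_rates(cfg, lab.suicidal_ideation, rng)
        n_tokens = int(rng.integers(cfg.tokens_min, cfg.tokens_max + 1))
        utterances = generate_transcript(rates, n_tokens, rng, cfg.pro_drop)
        turns = _utterances_to_turns(utterances, rng)
        write_transcript(turns, corpus_dir / f"{record.participant_id}.jsonl")
        true_rates[record.participant_id] = dict(rates, n_tokens=n_tokens)
    write_metadata(records, out_dir / "metadata.csv")
    rates_frame = pd.DataFrame.from_dict(true_rates, orient="index")
    rates_frame.index.name = "participant_id"
    rates_frame.to_csv(out_dir / "true_rates.csv")
    manifest = {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, ensure_ascii=False, sort_keys=True, indent=2,
                   default=str) + "\n",
        encoding="utf-8",
    )
    return out_dir


# ---------------------------------------------------------------------------
# Generator-implied association strength
# ---------------------------------------------------------------------------

def implied_crude_or(
    cfg: GeneratorConfig, feature: str, n_nodes: int = 4001
) -> float:
    """Population logistic projection of the generator's feature law.

    The generator specifies X | group as truncated normals, under which the
    induced model P(suicidal | X) is not exactly logistic; the implied
    crude odds ratio is defined as exp(b1) at the root of the population
    logistic score equations, computed by quadrature over both
    group-conditional distributions.
    """
    pi = cfg.prevalence
    nodes = []
    for suicidal, weight in ((False, 1 - pi), (True, pi)):
        mean, sd = cfg.group_rates(suicidal)[feature]
        dist = _truncnorm(mean, sd, 0.0)
        q = (np.arange(n_nodes) + 0.5) / n_nodes
        x = dist.ppf(q) if dist else np.full(n_nodes, mean)
        nodes.append((x, weight / n_nodes, 1.0 if suicidal else 0.0))

    def score(beta):
        b0, b1 = beta
        s0 = s1 = 0.0
        for x, w, y in nodes:
            p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
            s0 += w * np.sum(y - p)
            s1 += w * np.sum((y - p) * x)
        return [s0, s1]

    sol = optimize.root(score, x0=[np.log(pi / (1 - pi)), 0.0], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"implied-OR solver failed: {sol.message}")
    return float(np.exp(sol.x[1]))
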