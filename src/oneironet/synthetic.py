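"""Synthetic dream corpora and ordinal survey data.

The study's raw data are privately held, so this module generates
structurally faithful stand-ins:

* **Theme-structured corpora** — each report draws one latent theme (or
  none) with a stratum-specific prevalence; a fraction ``f`` of its
  tokens comes from the theme's word set and the remainder from a shared
  background vocabulary. The theme→word map is the *planted partition*
  the analysis pipeline is expected to recover; recovery is quantified
  with the adjusted Rand index.
* **Profile-exact corpora** — a constructive mode that reproduces the
  study corpus's size statistics exactly: total tokens and distinct word
  types, per stress stratum and overall, including the shared-type count
  those totals imply.
* **Ordinal surveys** — a Gaussian copula: a one-factor latent normal
  (the stress factor plus five sleep items) is discretized at the
  quantiles of the target marginals, with each latent correlation
  calibrated so the *discretized* pair attains a target Spearman rho.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from oneironet.corpus_io import DreamReport, Stratum, SurveyRecord

__all__ = [
    "ThemeSpec",
    "CorpusProfile",
    "SurveyProfile",
    "default_theme_specs",
    "default_corpus_profile",
    "default_survey_profile",
    "generate_corpus",
    "generate_paper_profile_corpus",
    "calibrate_copula",
    "generate_survey",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class ThemeSpec:
    """One latent dream theme.

    ``prevalence`` maps stratum → probability that a report of that
    stratum draws this theme; across themes the per-stratum prevalences
    must sum to at most 1 (the remainder are background-only reports).
    ``token_fraction`` is the expected share of a themed report's tokens
    drawn from the theme's word set. ``pandemic`` is annotation only.
    """

    theme_id: str
    words: tuple[str, ...]
    prevalence: Mapping[str, float]
    token_fraction: float = 0.8
    pandemic: bool = False

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("theme must have at least one word")
        if not 0 < self.token_fraction <= 1:
            raise ValueError("token_fraction must be in (0, 1]")
        if any(p < 0 for p in self.prevalence.values()):
            raise ValueError("prevalences must be non-negative")


def default_theme_specs(
    n_themes: int = 6,
    words_per_theme: int = 8,
    token_fraction: float = 0.8,
    prevalence: float = 0.15,
) -> list[ThemeSpec]:
    """Well-separated default themes: 6 themes × 8 disjoint words.

    Each stratum draws each theme with probability 0.15 (so 10% of
    reports are background-only), a regime in which the downstream
    pipeline should recover the planted partition cleanly.
    """
    strata = (Stratum.INCREASED.value, Stratum.UNCHANGED_LOWERED.value)
    themes = []
    for t in range(n_themes):
        words = tuple(f"t{t + 1}w{i + 1}" for i in range(words_per_theme))
        themes.append(ThemeSpec(
            theme_id=f"theme{t + 1}",
            words=words,
            prevalence={s: prevalence for s in strata},
            token_fraction=token_fraction,
            pandemic=(t % 2 == 0),
        ))
    return themes


def generate_corpus(
    themes: Sequence[ThemeSpec],
    reports_per_stratum: int = 400,
    background_vocab_size: int = 200,
    length_distribution: tuple[int, int] = (4, 10),
    seed: int = 0,
) -> tuple[list[DreamReport], dict[str, str]]:
    """Theme-structured corpus with a planted word partition.

    Returns ``(reports, planted)`` where ``planted`` maps each theme word
    to its theme id. Report lengths are uniform on the inclusive
    ``length_distribution`` range (minimum 2); token order within a
    report is randomized. Deterministic under ``seed``.
    """
    lo, hi = length_distribution
    if lo < 2 or hi < lo:
        raise ValueError("length_distribution must satisfy 2 <= lo <= hi")
    all_words: set[str] = set()
    for theme in themes:
        overlap = all_words & set(theme.words)
        if overlap:
            raise ValueError(f"theme word sets overlap: {sorted(overlap)[:5]}")
        all_words |= set(theme.words)
    strata = (Stratum.INCREASED, Stratum.UNCHANGED_LOWERED)
    for s in strata:
        total = sum(t.prevalence.get(s.value, 0.0) for t in themes)
        if total > 1 + 1e-9:
            raise ValueError(f"theme prevalences for {s.value!r} sum to {total} > 1")
    background = [f"bg{i + 1}" for i in range(background_vocab_size)]
    rng = np.random.default_rng(seed)
    reports: list[DreamReport] = []
    counter = 0
    for stratum in strata:
        probs = [t.prevalence.get(stratum.value, 0.0) for t in themes]
        probs.append(max(0.0, 1.0 - sum(probs)))
        for _ in range(reports_per_stratum):
            counter += 1
            choice = int(rng.choice(len(themes) + 1, p=np.asarray(probs) / sum(probs)))
            length = int(rng.integers(lo, hi + 1))
            tokens: list[str] = []
            if choice < len(themes):
                theme = themes[choice]
                n_theme = int(round(theme.token_fraction * length))
                n_theme = min(max(n_theme, 1), length)
                tokens += [str(w) for w in rng.choice(theme.words, size=n_theme)]
            else:
                n_theme = 0
            n_background = length - n_theme
            if n_background > 0:
                if not background:
                    raise ValueError(
                        "background_vocab_size=0 requires token_fraction=1 "
                        "and full theme coverage"
                    )
                tokens += [str(w) for w in rng.choice(background, size=n_background)]
            tokens = [tokens[i] for i in rng.permutation(len(tokens))]
            reports.append(DreamReport(
                report_id=f"r{counter:05d}",
                respondent_id=f"p{counter:05d}",
                stratum=stratum,
                tokens=tuple(tokens),
            ))
    planted = {w: t.theme_id for t in themes for w in t.words}
    return reports, planted


@dataclass(frozen=True)
class CorpusProfile:
    """Exact size statistics the profile-exact generator must reproduce.

    Defaults restate the harmonized study corpus: 4,743 tokens of 1,095
    distinct types overall; 3,226 tokens / 877 types in the
    stress-increased stratum and 1,514 / 589 in the unchanged/lowered
    stratum. The three tokens outside the two strata are modelled as an
    ``unspecified`` stratum that reuses existing types, which pins the
    number of types shared between the two main strata at
    877 + 589 − 1,095 = 371.
    """

    tokens_increased: int = 3226
    types_increased: int = 877
    tokens_unchanged_lowered: int = 1514
    types_unchanged_lowered: int = 589
    tokens_unspecified: int = 3
    total_tokens: int = 4743
    total_types: int = 1095

    @property
    def shared_types(self) -> int:
        return self.types_increased + self.types_unchanged_lowered - self.total_types

    def validate(self) -> None:
        if (self.tokens_increased + self.tokens_unchanged_lowered
                + self.tokens_unspecified != self.total_tokens):
            raise ValueError("stratum token counts do not sum to total_tokens")
        if self.types_increased > self.tokens_increased:
            raise ValueError("types_increased exceeds tokens_increased")
        if self.types_unchanged_lowered > self.tokens_unchanged_lowered:
            raise ValueError("types_unchanged_lowered exceeds tokens_unchanged_lowered")
        if self.shared_types < 0:
            raise ValueError("total_types exceeds the union of stratum types")
        if self.shared_types > min(self.types_increased, self.types_unchanged_lowered):
            raise ValueError("implied shared-type count exceeds a stratum's type count")
        if self.tokens_unspecified > 0 and self.total_types == 0:
            raise ValueError("unspecified tokens need existing types to reuse")


def default_corpus_profile() -> CorpusProfile:
    return CorpusProfile()


def _zipf_multinomial(rng: np.random.Generator, n_extra: int, n_types: int) -> np.ndarray:
    """Extra token counts per type under a Zipf-like (1/rank) law."""
    weights = 1.0 / np.arange(1, n_types + 1)
    return rng.multinomial(n_extra, weights / weights.sum())


def _chunk_reports(
    rng: np.random.Generator,
    tokens: list[str],
    stratum: Stratum,
    start_index: int,
    length_range: tuple[int, int] = (3, 9),
) -> list[DreamReport]:
    tokens = [tokens[i] for i in rng.permutation(len(tokens))]
    reports = []
    pos = 0
    idx = start_index
    while pos < len(tokens):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        chunk = tokens[pos:pos + length]
        pos += length
        idx += 1
        reports.append(DreamReport(
            report_id=f"r{idx:05d}", respondent_id=f"p{idx:05d}",
            stratum=stratum, tokens=tuple(chunk),
        ))
    return reports


def generate_paper_profile_corpus(
    profile: CorpusProfile | None = None, seed: int = 0
) -> list[DreamReport]:
    """Corpus whose size statistics match the profile *exactly*.

    Construction: the vocabulary is split into shared types (present in
    both main strata) and stratum-exclusive types; within each stratum
    every type appears once and the remaining token budget is spread with
    a Zipf-like law, which guarantees all token and type counts by
    construction — no rejection or repair is needed. Tokens are then
    shuffled and chunked into reports. Deterministic under ``seed``.
    """
    profile = profile or default_corpus_profile()
    profile.validate()
    rng = np.random.default_rng(seed)

    n_shared = profile.shared_types
    n_inc_only = profile.types_increased - n_shared
    n_ul_only = profile.types_unchanged_lowered - n_shared
    shared = [f"s{i + 1:04d}" for i in range(n_shared)]
    inc_only = [f"a{i + 1:04d}" for i in range(n_inc_only)]
    ul_only = [f"b{i + 1:04d}" for i in range(n_ul_only)]

    def stratum_tokens(types: list[str], n_tokens: int) -> list[str]:
        extra = _zipf_multinomial(rng, n_tokens - len(types), len(types))
        out: list[str] = []
        for word, extra_count in zip(types, extra):
            out += [word] * (1 + int(extra_count))
        return out

    reports: list[DreamReport] = []
    inc_tokens = stratum_tokens(shared + inc_only, profile.tokens_increased)
    reports += _chunk_reports(rng, inc_tokens, Stratum.INCREASED, 0)
    ul_tokens = stratum_tokens(shared + ul_only, profile.tokens_unchanged_lowered)
    reports += _chunk_reports(rng, ul_tokens, Stratum.UNCHANGED_LOWERED, len(reports))
    if profile.tokens_unspecified > 0:
        pool = shared or (inc_only + ul_only)
        unspec = [str(w) for w in rng.choice(pool, size=profile.tokens_unspecified)]
        reports.append(DreamReport(
            report_id=f"r{len(reports) + 1:05d}",
            respondent_id=f"p{len(reports) + 1:05d}",
            stratum=Stratum.UNSPECIFIED, tokens=tuple(unspec),
        ))
    return reports


# ---------------------------------------------------------------------------
# ordinal survey generation via a Gaussian copula


def _normalize(marginals: Sequence[float]) -> np.ndarray:
    """Normalize a marginal vector; printed percentage columns may sum to
    99.9/100.1 through per-cell rounding, anything further off is an error."""
    p = np.asarray(marginals, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 0.01:
        raise ValueError(f"marginals must sum to ~1, got {p.sum()}")
    return p / p.sum()


def _thresholds(marginals: Sequence[float]) -> np.ndarray:
    return sps.norm.ppf(np.cumsum(_normalize(marginals))[:-1])


def _discretized_spearman(latent_r: float, marg_a: Sequence[float],
                          marg_b: Sequence[float]) -> float:
    """Population Spearman of two ordinals from a discretized binormal.

    Spearman's rho with ties equals the Pearson correlation of the
    midrank CDF scores F(x−) + P(X=x)/2; cell probabilities come from
    bivariate-normal rectangle probabilities.
    """
    pa = _normalize(marg_a)
    pb = _normalize(marg_b)
    za = np.concatenate([[-np.inf], _thresholds(pa), [np.inf]])
    zb = np.concatenate([[-np.inf], _thresholds(pb), [np.inf]])
    mvn = sps.multivariate_normal(mean=[0.0, 0.0],
                                  cov=[[1.0, latent_r], [latent_r, 1.0]],
                                  allow_singular=True)
    grid = np.array([[mvn.cdf([x, y]) if np.isfinite(x) and np.isfinite(y)
                      else (0.0 if (x == -np.inf or y == -np.inf)
                            else 1.0)
                      for y in zb] for x in za])
    # rectangle probabilities need CDF values at semi-infinite corners too
    for i, x in enumerate(za):
        for j, y in enumerate(zb):
            if x == np.inf and np.isfinite(y):
                grid[i, j] = sps.norm.cdf(y)
            elif y == np.inf and np.isfinite(x):
                grid[i, j] = sps.norm.cdf(x)
    cells = (grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1])
    cells = np.clip(cells, 0.0, 1.0)
    u = np.concatenate([[0.0], np.cumsum(pa)])[:-1] + pa / 2.0
    v = np.concatenate([[0.0], np.cumsum(pb)])[:-1] + pb / 2.0
    mean_uv = float(u @ cells @ v)
    var_u = float(pa @ (u ** 2)) - 0.25
    var_v = float(pb @ (v ** 2)) - 0.25
    return (mean_uv - 0.25) / math.sqrt(var_u * var_v)


def calibrate_copula(
    target_rho: float,
    marginals_a: Sequence[float],
    marginals_b: Sequence[float],
    tol: float = 0.005,
) -> float:
    """Latent binormal correlation whose discretized pair hits ``target_rho``.

    The discretized Spearman is strictly increasing in the latent
    correlation, so a bisection converges; an unattainable target (beyond
    what the marginals allow) raises with the attainable range.
    """
    if target_rho == 0.0:
        return 0.0
    lo, hi = -0.9999, 0.9999
    rho_lo = _discretized_spearman(lo, marginals_a, marginals_b)
    rho_hi = _discretized_spearman(hi, marginals_a, marginals_b)
    if not rho_lo - tol <= target_rho <= rho_hi + tol:
        raise ValueError(
            f"target Spearman {target_rho} unattainable; range is "
            f"[{rho_lo:.4f}, {rho_hi:.4f}] under these marginals"
        )
    for _ in range(60):
        mid = (lo + hi) / 2.0
        rho_mid = _discretized_spearman(mid, marginals_a, marginals_b)
        if abs(rho_mid - target_rho) <= tol * 0.5:
            return mid
        if rho_mid < target_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class SurveyProfile:
    """Marginals and Spearman targets for the survey generator.

    Defaults restate the study survey: n = 4,275 respondents; stress
    marginals (lowered → high increase) 22.1/21.9/38.0/18.0%; per-item
    three-category marginals in the worsening direction
    (improved/no change/worsened); Spearman targets of each item with
    stress of 0.26 (duration), 0.37 (latency), 0.43 (awakenings), 0.182
    (regularity) and 0.29 (nightmares); dream-reporting probabilities per
    stress level of 17.8/13.0/20.5/27.4%.
    """

    n: int = 4275
    stress_marginals: tuple[float, ...] = (0.221, 0.219, 0.380, 0.180)
    item_marginals: Mapping[str, tuple[float, ...]] = field(default_factory=lambda: {
        "sleep_duration": (0.542, 0.291, 0.166),
        "sleep_latency": (0.130, 0.774, 0.096),
        "awakenings": (0.117, 0.597, 0.286),
        "sleep_regularity": (0.299, 0.538, 0.163),
        "nightmares": (0.035, 0.704, 0.260),
    })
    item_targets: Mapping[str, float] = field(default_factory=lambda: {
        "sleep_duration": 0.26,
        "sleep_latency": 0.37,
        "awakenings": 0.43,
        "sleep_regularity": 0.182,
        "nightmares": 0.29,
    })
    dream_report_prob: tuple[float, ...] = (0.178, 0.130, 0.205, 0.274)
    sex_marginals: tuple[float, ...] = (0.79, 0.19, 0.02)
    age_band_edges: tuple[tuple[int, int], ...] = (
        (10, 19), (20, 34), (35, 49), (50, 64), (65, 85))
    age_band_probs: tuple[float, ...] = (0.022, 0.301, 0.365, 0.236, 0.076)

    def validate(self) -> None:
        for name, marg in [("stress", self.stress_marginals),
                           *self.item_marginals.items()]:
            _normalize(marg)  # raises on bad vectors
        for item, rho in self.item_targets.items():
            if not -1 < rho < 1:
                raise ValueError(f"target rho for {item} outside (-1, 1)")


def default_survey_profile() -> SurveyProfile:
    return SurveyProfile()


def generate_survey(profile: SurveyProfile | None = None, seed: int = 0) -> list[SurveyRecord]:
    """Ordinal survey records with copula-calibrated Spearman structure.

    A one-factor latent normal is used: the stress latent is the common
    factor and each sleep item loads on it with its calibrated latent
    correlation, which makes the joint correlation matrix positive
    semidefinite by construction. Latents are discretized at the marginal
    quantiles; demographics and dream reporting are drawn from the
    profile's categorical distributions (reporting probability depends on
    stress level). Deterministic under ``seed``.
    """
    profile = profile or default_survey_profile()
    profile.validate()
    items = list(profile.item_marginals)
    loadings = {
        item: calibrate_copula(profile.item_targets[item],
                               profile.stress_marginals,
                               profile.item_marginals[item])
        for item in items
    }
    rng = np.random.default_rng(seed)
    n = profile.n
    g = rng.standard_normal(n)
    stress = np.searchsorted(_thresholds(profile.stress_marginals), g) + 1
    ordinals: dict[str, np.ndarray] = {}
    for item in items:
        v = loadings[item]
        latent = v * g + math.sqrt(max(0.0, 1.0 - v * v)) * rng.standard_normal(n)
        ordinals[item] = np.searchsorted(_thresholds(profile.item_marginals[item]),
                                         latent) + 1
    sexes = rng.choice(["female", "male", "other_unspecified"], size=n,
                       p=profile.sex_marginals)
    bands = rng.choice(len(profile.age_band_probs), size=n, p=profile.age_band_probs)
    ages = np.array([rng.integers(profile.age_band_edges[b][0],
                                  profile.age_band_edges[b][1] + 1) for b in bands])
    report_p = np.asarray(profile.dream_report_prob)[stress - 1]
    reported = rng.random(n) < report_p
    return [
        SurveyRecord(
            respondent_id=f"p{i + 1:05d}",
            age=int(ages[i]),
            sex=str(sexes[i]),
            stress_change=int(stress[i]),
            sleep_duration=int(ordinals["sleep_duration"][i]),
            sleep_latency=int(ordinals["sleep_latency"][i]),
            awakenings=int(ordinals["awakenings"][i]),
            sleep_regularity=int(ordinals["sleep_regularity"][i]),
            nightmares=int(ordinals["nightmares"][i]),
            reported_dream=bool(reported[i]),
        )
        for i in range(n)
    ]


def adjusted_rand_index(partition_a: Mapping[str, object],
                        partition_b: Mapping[str, object]) -> float:
    """Pair-counting adjusted Rand index; 1 iff identical up to relabeling."""
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions are over different node sets")
    nodes = sorted(partition_a)
    labels_a = {lab: i for i, lab in enumerate(dict.fromkeys(partition_a[v] for v in nodes))}
    labels_b = {lab: i for i, lab in enumerate(dict.fromkeys(partition_b[v] for v in nodes))}
    table = np.zeros((len(labels_a), len(labels_b)), dtype=np.int64)
    for v in nodes:
        table[labels_a[partition_a[v]], labels_b[partition_b[v]]] += 1

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    n = len(nodes)
    sum_cells = comb2(table)
    sum_rows = comb2(table.sum(axis=1))
    sum_cols = comb2(table.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)
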