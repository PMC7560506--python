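"""Deterministic token harmonization.

Dream transcripts arrive as ordered noun lists. Harmonization collapses
synonym/spelling variants onto one chosen word and groups open-ended word
classes under a category token (specific cities → "city", distant kin →
"relative"), while a keep-list protects tokens that stay as themselves
(father, mother, country names). Duplicates are retained so the
chronological structure of the dream survives: if a word appeared twice
in the transcript it appears twice in the harmonized list.

The synonym map is applied before the category map so category rules
operate on canonical forms. Rules are validated to be an idempotent
closure, hence ``harmonize(harmonize(x)) == harmonize(x)``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from oneironet.corpus_io import DreamReport, HarmonizationRules

__all__ = ["harmonize_tokens", "harmonize_report", "harmonize_reports"]


def harmonize_tokens(tokens: Sequence[str], rules: HarmonizationRules) -> list[str]:
    """Apply synonym then category rules to each token, preserving order.

    Output has the same length as the input; unknown tokens pass through
    unchanged; keep-listed tokens are exempt from category grouping (but
    not from synonym normalization).
    """
    out = []
    for token in tokens:
        token = rules.synonym_map.get(token, token)
        if token not in rules.keep:
            token = rules.category_map.get(token, token)
        out.append(token)
    return out


def harmonize_report(report: DreamReport, rules: HarmonizationRules) -> DreamReport:
    return replace(report, tokens=tuple(harmonize_tokens(report.tokens, rules)))


def harmonize_reports(
    reports: Sequence[DreamReport], rules: HarmonizationRules
) -> list[DreamReport]:
    return [harmonize_report(r, rules) for r in reports]
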