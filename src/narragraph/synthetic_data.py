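"""Synthetic narratives and cohorts with known recurrence structure.

Token streams come from a three-branch process: with probability
``p_repeat`` the previous token is emitted again (driving self-loops),
with probability ``p_backref`` a token is drawn uniformly from the last
``lag`` distinct tokens excluding the previous one (driving repeated
edges and strongly connected structure), and with the remaining mass a
fresh vocabulary token is drawn uniformly, excluding the previous token.
Because only the repeat branch can emit the previous token, the expected
self-loop count per transition is exactly ``p_repeat``.

Cohorts link symptom counts S (0-18) to narrative mechanics through
``p_repeat(S)`` (increasing), ``p_backref(S)`` (decreasing) and
narrative length (increasing), with covariates drawn independently of S
by default.  Everything is reproducible from the seed, and all outputs
are written in exactly the formats the analysis pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scales import DEFAULT_DOMAIN_MAP, HYPERACTIVITY, INATTENTION
from .text_processing import TokenSequence

__all__ = [
    "NarrativeGeneratorParams",
    "CohortGeneratorParams",
    "generate_narrative",
    "generate_asrs_items",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class NarrativeGeneratorParams:
    # large default vocabulary keeps accidental word collisions (which
    # close long cycles and inflate LSC) negligible next to p_backref
    vocab_size: int = 5000
    length: int = 120
    p_repeat: float = 0.1
    p_backref: float = 0.2
    lag: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.lag < 2:
            raise ValueError("lag must be >= 2")
        if self.p_repeat < 0 or self.p_backref < 0:
            raise ValueError("branch probabilities must be non-negative")
        if self.p_repeat + self.p_backref > 1.0 + 1e-12:
            raise ValueError("p_repeat + p_backref must not exceed 1")


def _vocab(size: int) -> list[str]:
    width = max(3, len(str(size)))
    return [f"w{i:0{width}d}" for i in range(1, size + 1)]


def generate_narrative(
    params: NarrativeGeneratorParams,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> TokenSequence:
    """Sample one token stream from the three-branch process."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vocab = _vocab(params.vocab_size)
    tokens: list[str] = [vocab[rng.integers(len(vocab))]]
    recent: list[str] = [tokens[0]]  # distinct tokens, most recent last
    while len(tokens) < params.length:
        prev = tokens[-1]
        u = rng.random()
        if u < params.p_repeat:
            nxt = prev
        else:
            candidates = [t for t in recent[-params.lag :] if t != prev]
            if u < params.p_repeat + params.p_backref and candidates:
                nxt = candidates[rng.integers(len(candidates))]
            else:
                nxt = prev
                while nxt == prev:
                    nxt = vocab[rng.integers(len(vocab))]
        tokens.append(nxt)
        if nxt in recent:
            recent.remove(nxt)
        recent.append(nxt)
    return TokenSequence(
        subject_id=subject_id,
        tokens=tuple(tokens),
        raw_token_count=len(tokens),
    )


@dataclass(frozen=True)
class CohortGeneratorParams:
    """Cohort-level linkage between symptom counts and narratives.

    ``p_repeat(S) = p_repeat_base + p_repeat_slope * S`` and likewise
    for p_backref; narrative length is
    ``base_length + length_increment * S``.  Slopes of zero give a null
    cohort with no symptom-narrative association.
    """

    n_subjects: int = 60
    vocab_size: int = 5000
    lag: int = 8
    base_length: int = 90
    length_increment: int = 2
    p_repeat_base: float = 0.05
    p_repeat_slope: float = 0.012
    p_backref_base: float = 0.32
    p_backref_slope: float = -0.012
    symptom_range: tuple[int, int] = (0, 18)
    covariate_means: dict = field(
        default_factory=lambda: {
            "age": 26.0,
            "iq": 110.0,
            "education_years": 17.0,
            "bdi": 8.0,
            "stai_state": 38.0,
            "stai_trait": 40.0,
            "upps_total": 90.0,
        }
    )
    covariate_scales: dict = field(
        default_factory=lambda: {
            "age": 5.0,
            "iq": 12.0,
            "education_years": 2.0,
            "bdi": 5.0,
            "stai_state": 8.0,
            "stai_trait": 8.0,
            "upps_total": 12.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.symptom_range
        if not (0 <= lo <= hi <= 18):
            raise ValueError("symptom_range must lie within [0, 18]")
        for s in (lo, hi):
            pr = self.p_repeat_base + self.p_repeat_slope * s
            pb = self.p_backref_base + self.p_backref_slope * s
            if pr < 0 or pb < 0 or pr + pb > 1:
                raise ValueError(
                    f"branch probabilities invalid at symptom count {s}: "
                    f"p_repeat={pr:.3f}, p_backref={pb:.3f}"
                )
        if self.base_length < 2:
            raise ValueError("base_length must be >= 2")

    def p_repeat(self, s: int) -> float:
        return self.p_repeat_base + self.p_repeat_slope * s

    def p_backref(self, s: int) -> float:
        return self.p_backref_base + self.p_backref_slope * s

    def length(self, s: int) -> int:
        return self.base_length + self.length_increment * s


def generate_asrs_items(
    s_inattention: int, s_hyperactivity: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Item vector whose positive-symptom counts equal the given scores.

    Positive items are rated 2 or 3, the rest 0 or 1, so rescoring the
    vector recovers the domain counts exactly.
    """
    items = np.zeros(18, dtype=int)
    inatt_idx = [i for i, d in enumerate(DEFAULT_DOMAIN_MAP) if d == INATTENTION]
    hyper_idx = [i for i, d in enumerate(DEFAULT_DOMAIN_MAP) if d == HYPERACTIVITY]
    pos_inatt = rng.choice(inatt_idx, size=s_inattention, replace=False)
    pos_hyper = rng.choice(hyper_idx, size=s_hyperactivity, replace=False)
    for idx in list(pos_inatt) + list(pos_hyper):
        items[idx] = rng.integers(2, 4)
    for idx in range(18):
        if items[idx] == 0:
            items[idx] = rng.integers(0, 2)
    return tuple(int(v) for v in items)


def generate_cohort(
    params: CohortGeneratorParams,
) -> tuple[list[TokenSequence], pd.DataFrame]:
    """Sample a full cohort: one narrative + metadata row per subject."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.symptom_range
    narratives = []
    rows = []
    for i in range(params.n_subjects):
        sid = f"subj{i + 1:03d}"
        s_total = int(rng.integers(lo, hi + 1))
        s_inatt = int(rng.binomial(s_total, 0.5)) if s_total else 0
        s_inatt = min(s_inatt, 9)
        s_hyper = s_total - s_inatt
        if s_hyper > 9:
            s_inatt += s_hyper - 9
            s_hyper = 9
        nar_params = NarrativeGeneratorParams(
            vocab_size=params.vocab_size,
            length=params.length(s_total),
            p_repeat=params.p_repeat(s_total),
            p_backref=params.p_backref(s_total),
            lag=params.lag,
            seed=params.seed,
        )
        narratives.append(generate_narrative(nar_params, rng=rng, subject_id=sid))
        row: dict = {"subject_id": sid}
        items = generate_asrs_items(s_inatt, s_hyper, rng)
        for j, v in enumerate(items, start=1):
            row[f"asrs_{j:02d}"] = v
        for name, mean in params.covariate_means.items():
            scale = params.covariate_scales.get(name, 1.0)
            row[name] = round(float(rng.normal(mean, scale)), 2)
        rows.append(row)
    return narratives, pd.DataFrame(rows)


def write_cohort(
    narratives: Sequence[TokenSequence],
    metadata: pd.DataFrame,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write transcripts/ directory and subjects.csv under ``outdir``."""
    outdir = Path(outdir)
    tdir = outdir / "transcripts"
    tdir.mkdir(parents=True, exist_ok=True)
    for seq in narratives:
        (tdir / f"{seq.subject_id}.txt").write_text(
            " ".join(seq.tokens) + "\n", encoding="utf-8"
        )
    meta_path = outdir / "subjects.csv"
    metadata.to_csv(meta_path, index=False)
    return tdir, meta_path
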