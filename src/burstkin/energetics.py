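"""Nearest-neighbour duplex energetics for guide:target RNA pairs.

ΔG°37 of the contiguously paired span is computed as helix initiation plus the
sum of stacked-dinucleotide terms plus terminal A-U penalties, using a
published RNA/RNA Watson–Crick parameter set shipped as package data
(``nn_rna_wc_1998``).  Guide coordinates are 1-based, 5'→3'; position g1 is
anchored in the protein and never counted as paired, so spans start at g2.
Wobble pairs are not admitted into spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RnaGuide",
    "PairedSpan",
    "NNTable",
    "load_nn_table",
    "pairing_span",
    "duplex_dg37",
    "energy_rate_table",
]

_ALPHABET = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_TABLE = "nn_rna_wc_1998"


def _validate_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class RnaGuide:
    """A guide RNA, 5'→3', with optional 3'-terminal 2'-O-methyl flag.

    The 2'-O-methyl modification is treated as thermodynamically neutral.
    """

    sequence: str
    three_prime_2ome: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_rna(self.sequence, "guide"))
        if not 10 <= len(self.sequence) <= 40:
            raise ValueError(f"guide length must be in [10, 40], got {len(self.sequence)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairedSpan:
    """Contiguous Watson–Crick paired run, 1-based inclusive guide coordinates."""

    g_start: int
    g_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.g_start <= self.g_end:
            raise ValueError(f"invalid span ({self.g_start}, {self.g_end})")

    @property
    def n_pairs(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass(frozen=True)
class NNTable:
    """Nearest-neighbour parameter set (kcal/mol at 37 °C)."""

    name: str
    stacks: dict
    init: float
    terminal_au: float
    symmetry: float

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.stacks.values()):
            raise ValueError("all stack terms must be negative")
        if self.init <= 0:
            raise ValueError("initiation term must be positive")


def load_nn_table(name: str = DEFAULT_TABLE) -> NNTable:
    """Load a nearest-neighbour table shipped as package data."""
    path = resources.files("burstkin.data").joinpath(f"{name}.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    terms = dict(zip(df["step"], df["dg37_kcal_mol"]))
    stacks = {k: float(v) for k, v in terms.items() if len(k) == 2 and set(k) <= _ALPHABET}
    if len(stacks) != 16:
        raise ValueError(f"table {name} must define all 16 stack steps, has {len(stacks)}")
    return NNTable(
        name=name,
        stacks=stacks,
        init=float(terms["init"]),
        terminal_au=float(terms["terminal_au"]),
        symmetry=float(terms["symmetry"]),
    )


def _is_wc(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def pairing_span(guide: RnaGuide, target: str) -> PairedSpan:
    """Locate the contiguous complementary run starting at guide position 2.

    The target (5'→3') is reversed to bring it into antiparallel register with
    the guide; every register in which g2 forms a Watson–Crick pair is
    extended 3'-ward along the guide, and the longest run wins.  No pairing at
    g2 in any register is an error.
    """
    g = guide.sequence
    t_rev = _validate_rna(target, "target")[::-1]
    best: PairedSpan | None = None
    # register r: guide position i (1-based) pairs t_rev[i - 1 + r]
    for r in range(-1, len(t_rev) - 1):
        j2 = 1 + r  # 0-based index in t_rev opposite g2
        if not 0 <= j2 < len(t_rev) or not _is_wc(g[1], t_rev[j2]):
            continue
        end = 2
        for i in range(3, guide.length + 1):
            j = i - 1 + r
            if j >= len(t_rev) or not _is_wc(g[i - 1], t_rev[j]):
                break
            end = i
        if best is None or end > best.g_end:
            best = PairedSpan(2, end)
    if best is None:
        raise ValueError("no seed-adjacent pairing: target does not pair guide position 2")
    return best


def duplex_dg37(
    guide: RnaGuide,
    target: str | None = None,
    span: PairedSpan | None = None,
    table: NNTable | None = None,
    include_init: bool = True,
    include_terminal: bool = True,
) -> float:
    """ΔG°37 (kcal/mol) of the paired span; more negative = tighter.

    ΔG = initiation + Σ stack terms over consecutive pairs + terminal A-U
    penalties at both helix ends, plus the symmetry correction when the span
    duplex is self-complementary.  A single-pair span has no stacks and
    returns initiation plus penalties only.  If ``target`` is given, the span
    is verified to lie inside the located complementary run (and defaults to
    that run when ``span`` is omitted).  ``include_init`` /
    ``include_terminal`` give a stacks-only mode; outputs should record which
    mode was used.
    """
    if table is None:
        table = load_nn_table()
    if target is not None:
        found = pairing_span(guide, target)
        if span is None:
            span = found
        elif not (found.g_start <= span.g_start and span.g_end <= found.g_end):
            raise ValueError(
                f"span {span} is not Watson-Crick paired against the target (run {found})"
            )
    if span is None:
        raise ValueError("either a target or an explicit span is required")
    g = guide.sequence
    if span.g_end > guide.length:
        raise ValueError("span extends beyond guide")
    dg = 0.0
    if include_init:
        dg += table.init
    for i in range(span.g_start, span.g_end):  # stack between pair i and i+1
        dg += table.stacks[g[i - 1] + g[i]]
    if include_terminal:
        for pos in (span.g_start, span.g_end):
            if g[pos - 1] in "AU":
                dg += table.terminal_au
    top = g[span.g_start - 1: span.g_end]
    if top == "".join(_COMPLEMENT[b] for b in reversed(top)):
        dg += table.symmetry
    return dg


def energy_rate_table(entries) -> dict:
    """Associate duplex energy with fitted rates across a guide panel.

    ``entries`` is an iterable of ``(guide_length, dg37, k_burst, k_ss)``.
    Returns the table sorted by ΔG together with Spearman rank correlations
    of ΔG against each rate (midranks under ties).
    """
    df = pd.DataFrame(entries, columns=["guide_length_nt", "dg37_kcal_mol",
                                        "k_burst_per_min", "k_ss_per_min"])
    if len(df) < 3:
        raise ValueError(f"need >= 3 entries, got {len(df)}")
    df = df.sort_values("dg37_kcal_mol").reset_index(drop=True)
    rho_burst = float(stats.spearmanr(df["dg37_kcal_mol"], df["k_burst_per_min"]).statistic)
    rho_ss = float(stats.spearmanr(df["dg37_kcal_mol"], df["k_ss_per_min"]).statistic)
    return {
        "table": df,
        "spearman_dg_kburst": rho_burst,
        "spearman_dg_kss": rho_ss,
    }
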