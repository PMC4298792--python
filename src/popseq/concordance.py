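"""Validation statistics for an anchored assembly.

Three checks mirror how an anchoring is validated in practice:

* short-range concordance (:func:`pair_concordance`): pairs of contigs known
  to be physically close (e.g. on the same ~100-200 kb BAC clone) should
  receive the same chromosome and nearby cM positions;
* problematic-clone flagging (:func:`flag_problematic_clones`): clones whose
  contigs split between two chromosomes, or with implausibly large insert
  sizes, point at chimeric or mislabeled clones rather than anchoring errors;
* cross-map concordance (:func:`cross_anchoring_concordance`): the same
  contigs anchored against two independent framework maps should agree.

:func:`lander_waterman_covered_fraction` gives the expected genome fraction
covered at fold-coverage c under the Lander-Waterman model, ``1 - e^(-c)`` --
the link between sequencing depth and the genotype call rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .anchoring import ANCHORED, ContigAnchor

log = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    """Classification of physically linked contig pairs by genetic agreement.

    The three fractions are over classified pairs and sum to 1.
    """

    n_pairs: int
    frac_same_chromosome_within_window: float
    frac_same_chrom_beyond_window: float
    frac_discordant_chromosome: float
    window_cm: float


@dataclass
class CrossMapReport:
    """Agreement of two anchorings of the same contigs."""

    n_common: int
    frac_discordant_chromosome: float
    frac_beyond_window: float
    window_cm: float


def _anchored_lookup(anchors: Iterable[ContigAnchor]) -> dict[str, tuple[str, float]]:
    return {
        a.contig_id: (a.chromosome, a.cm)
        for a in anchors
        if a.status == ANCHORED
    }


def pair_concordance(
    anchors: Iterable[ContigAnchor],
    links: pd.DataFrame,
    window_cm: float = 3.0,
) -> ConcordanceReport:
    """Classify every unordered pair of anchored contigs sharing a clone.

    ``links`` is a table with columns ``clone_id, contig_id``.  Each pair is
    discordant-chromosome, same-chromosome-within-window (|dcm| <=
    ``window_cm``) or same-chromosome-beyond-window; fractions are over
    classified pairs (pairs with an unanchored member are not classified).
    """
    pos = _anchored_lookup(anchors)
    n_within = n_beyond = n_disc = 0
    for _, grp in links.groupby("clone_id", sort=False):
        members = [c for c in grp["contig_id"].astype(str).unique() if c in pos]
        for a, b in combinations(sorted(members), 2):
            (ca, cma), (cb, cmb) = pos[a], pos[b]
            if ca != cb:
                n_disc += 1
            elif abs(cma - cmb) <= window_cm:
                n_within += 1
            else:
                n_beyond += 1
    n = n_within + n_beyond + n_disc
    if n == 0:
        log.warning("pair_concordance: no classifiable contig pairs")
        return ConcordanceReport(0, np.nan, np.nan, np.nan, window_cm)
    return ConcordanceReport(
        n_pairs=n,
        frac_same_chromosome_within_window=n_within / n,
        frac_same_chrom_beyond_window=n_beyond / n,
        frac_discordant_chromosome=n_disc / n,
        window_cm=window_cm,
    )


def flag_problematic_clones(
    anchors: Iterable[ContigAnchor],
    links: pd.DataFrame,
    second_chrom_frac: float = 0.30,
    max_clone_length: int = 180_000,
    min_anchored: int = 5,
) -> list[tuple[str, str]]:
    """Flag clones whose anchored contigs disagree suspiciously.

    Only clones with at least ``min_anchored`` anchored contigs *and*
    discordant chromosome assignments are examined.  A clone is flagged
    ``SPLIT`` when the chromosome with the second-highest contig count holds
    at least ``second_chrom_frac`` of its anchored contigs, and additionally
    ``OVERSIZED`` when its recorded length is >= ``max_clone_length`` bp
    (suggestive of a chimeric insert).  Output is sorted by clone id and is
    independent of link-row order.
    """
    pos = _anchored_lookup(anchors)
    has_length = "clone_length" in links.columns
    flags: list[tuple[str, str]] = []
    for clone_id, grp in links.groupby("clone_id", sort=True):
        chroms = [pos[c][0] for c in grp["contig_id"].astype(str).unique() if c in pos]
        if len(chroms) < min_anchored or len(set(chroms)) < 2:
            continue
        counts = pd.Series(chroms).value_counts()
        if counts.iloc[1] / len(chroms) >= second_chrom_frac:
            flags.append((str(clone_id), "SPLIT"))
        if has_length:
            length = grp["clone_length"].iloc[0]
            if not pd.isna(length) and length >= max_clone_length:
                flags.append((str(clone_id), "OVERSIZED"))
    return sorted(flags)


def cross_anchoring_concordance(
    a: Iterable[ContigAnchor],
    b: Iterable[ContigAnchor],
    projection: Callable[[str, float], float] | None = None,
    window_cm: float = 5.0,
) -> CrossMapReport:
    """Compare two anchorings of overlapping contig sets.

    Over contigs anchored in both: the fraction with discordant chromosome,
    and -- among chromosome-concordant contigs -- the fraction whose cM
    positions differ by more than ``window_cm`` after optionally projecting
    b's coordinates onto a's scale with ``projection(chromosome, cm)``.
    """
    pa, pb = _anchored_lookup(a), _anchored_lookup(b)
    common = sorted(set(pa) & set(pb))
    if not common:
        log.warning("cross_anchoring_concordance: no contigs anchored in both sets")
        return CrossMapReport(0, np.nan, np.nan, window_cm)
    n_disc = 0
    n_beyond = 0
    n_same = 0
    for cid in common:
        (ca, cma), (cb, cmb) = pa[cid], pb[cid]
        if ca != cb:
            n_disc += 1
            continue
        n_same += 1
        if projection is not None:
            cmb = projection(cb, cmb)
        if abs(cma - cmb) > window_cm:
            n_beyond += 1
    return CrossMapReport(
        n_common=len(common),
        frac_discordant_chromosome=n_disc / len(common),
        frac_beyond_window=(n_beyond / n_same) if n_same else np.nan,
        window_cm=window_cm,
    )


def lander_waterman_covered_fraction(depth):
    """Expected covered genome fraction at fold-coverage ``depth``: 1 - e^-c."""
    c = np.asarray(depth, dtype=float)
    if np.any(c < 0):
        raise ValueError("fold-coverage must be >= 0")
    f = 1.0 - np.exp(-c)
    return f if f.ndim else float(f)
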