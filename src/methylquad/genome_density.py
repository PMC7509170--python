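"""DMC density in centromeric versus other chromosome regions.

The centromere of a chromosome is taken as the union of its p11.1 and
q11.1 cytogenetic subbands (GRCh37-style cytoband coordinates, 0-based
half-open); everything else on the chromosome is "other regions". DMC
positions (1-based) are assigned by point-in-interval membership and
densities are reported per megabase, rounded half-up to two decimals for
display while full precision is kept internally.

The pooled difference test asks whether DMC counts split between the two
compartments proportionally to their pooled lengths: an exact binomial
test for small totals, a chi-square goodness-of-fit test otherwise.
"""
from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CytobandTable, Manifest

logger = logging.getLogger(__name__)

MB = 1_000_000.0
CENTROMERE_BANDS = ("p11.1", "q11.1")
#: totals up to this use the exact binomial test
BINOMIAL_MAX_TOTAL = 500


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (3.335 -> 3.34), for display columns."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def centromere_intervals(cytobands: CytobandTable) -> dict[str, dict]:
    """Per-chromosome centromere intervals and total length.

    Returns ``{chrom: {"centromere": [(start, end), ...], "length": L}}``
    with 0-based half-open base-pair intervals. A chromosome missing one
    of the two pericentromeric bands uses whichever is available (with a
    warning); one missing both gets an empty centromere.
    """
    lengths = cytobands.chromosome_lengths()
    out: dict[str, dict] = {}
    for chrom, grp in cytobands.bands.groupby("chromosome"):
        cent = grp[grp["band"].isin(CENTROMERE_BANDS)].sort_values("start")
        if len(cent) < 2:
            logger.warning(
                "chromosome %s has %d of 2 pericentromeric bands", chrom, len(cent)
            )
        out[chrom] = {
            "centromere": [(int(s), int(e)) for s, e in zip(cent["start"], cent["end"])],
            "length": int(lengths[chrom]),
        }
    return out


def _in_intervals(pos0: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def densities_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add density columns to a table of per-chromosome counts and lengths.

    Input columns: chromosome, centromere_length_mb, other_length_mb,
    dmcs_centromere, dmcs_other. Densities are count/length in n/Mb with
    half-up 2-decimal display rounding; *_exact columns keep full
    precision.
    """
    out = counts.copy()
    if (out["centromere_length_mb"] <= 0).any() or (out["other_length_mb"] <= 0).any():
        raise ValueError("region lengths must be positive")
    out["density_centromere_exact"] = out["dmcs_centromere"] / out["centromere_length_mb"]
    out["density_other_exact"] = out["dmcs_other"] / out["other_length_mb"]
    out["density_centromere"] = out["density_centromere_exact"].map(round_half_up)
    out["density_other"] = out["density_other_exact"].map(round_half_up)
    return out


def density_table(
    dmc_probe_ids: list[str] | pd.Index,
    manifest: Manifest,
    intervals: dict[str, dict],
) -> pd.DataFrame:
    """Per-chromosome DMC counts and densities in centromere vs elsewhere.

    1-based manifest positions are converted to the bands' 0-based
    half-open system before membership tests; a boundary position belongs
    to the band whose half-open interval contains it. DMCs on
    chromosomes absent from the cytoband table are excluded with a
    warning.
    """
    positions = manifest.probe_positions()
    positions = positions[positions["probe_id"].isin(set(dmc_probe_ids))]
    unknown = set(positions["chromosome"]) - set(intervals)
    if unknown:
        n = int(positions["chromosome"].isin(unknown).sum())
        logger.warning("excluding %d DMCs on chromosomes without cytobands: %s", n, sorted(unknown))
        positions = positions[~positions["chromosome"].isin(unknown)]
    rows = []
    for chrom in sorted(intervals, key=lambda c: (len(c), c)):
        info = intervals[chrom]
        cent_len = sum(e - s for s, e in info["centromere"])
        other_len = info["length"] - cent_len
        here = positions[positions["chromosome"] == chrom]
        in_cent = sum(_in_intervals(p - 1, info["centromere"]) for p in here["position"])
        rows.append(
            {
                "chromosome": chrom,
                "centromere_length_mb": cent_len / MB,
                "other_length_mb": other_len / MB,
                "dmcs_centromere": int(in_cent),
                "dmcs_other": int(len(here) - in_cent),
            }
        )
    return densities_from_counts(pd.DataFrame(rows))


def density_difference_test(table: pd.DataFrame) -> tuple[str, float, float]:
    """Pooled two-sided test of proportional-to-length DMC placement.

    Returns (test_name, statistic, p). The null expects the pooled DMC
    count to split between centromere and other compartments in
    proportion to their pooled lengths.
    """
    k_cent = int(table["dmcs_centromere"].sum())
    k_other = int(table["dmcs_other"].sum())
    total = k_cent + k_other
    if total == 0:
        raise ValueError("no DMCs: density difference test undefined")
    l_cent = float(table["centromere_length_mb"].sum())
    l_other = float(table["other_length_mb"].sum())
    p0 = l_cent / (l_cent + l_other)
    if total <= BINOMIAL_MAX_TOTAL:
        res = stats.binomtest(k_cent, total, p0, alternative="two-sided")
        return "binomial_exact", float(k_cent), float(res.pvalue)
    expected = np.array([total * p0, total * (1 - p0)])
    chi2, p = stats.chisquare([k_cent, k_other], expected)
    return "chi_square_gof", float(chi2), float(p)
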