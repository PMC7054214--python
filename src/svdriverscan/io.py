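"""Readers and writers for the external formats the toolkit touches.

Formats: BEDPE (rearrangements, 0-based half-open, >=10 columns), BED4
(elements, merged per id), bedGraph-like 4-column TSV (covariate tracks),
and headered TSV for mutations and all tabular outputs.  MAF-like
mutation tables may be declared 1-based (``one_based=True``) in which case
positions are converted explicitly on input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (CovariateTrack, Element, GenomeDef, MutationRecord,
                     ParameterError, Breakpoint, Rearrangement, SV_CLASSES,
                     make_bins)

log = logging.getLogger("svdriverscan")

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2"]


class ParseError(ValueError):
    """Malformed input row; carries the 1-based line number."""

    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


def read_bedpe(path, genome: Optional[GenomeDef] = None,
               sample_column: str = "name") -> list[Rearrangement]:
    """Read rearrangements from a BEDPE file.

    The breakpoint position of each end is the lower (start) coordinate of
    the end interval.  The sample ID is taken from the ``name`` column by
    default, or from an 11th column when ``sample_column="extra"``.  The
    SV class is parsed from the name when formatted ``sample:CLASS``.
    Records on chromosomes absent from ``genome`` are skipped with a
    logged count.
    """
    path = Path(path)
    rearrs: list[Rearrangement] = []
    n_skipped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(path, line_no, f"expected >=10 columns, got {len(fields)}")
            try:
                c1, s1 = fields[0], int(fields[1])
                c2, s2 = fields[3], int(fields[4])
                int(fields[2]), int(fields[5])
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad coordinate: {exc}") from None
            if genome is not None and (c1 not in genome or c2 not in genome):
                n_skipped += 1
                continue
            if sample_column == "extra":
                if len(fields) < 11:
                    raise ParseError(path, line_no, "sample column 11 missing")
                sample, sv_class = fields[10], "unknown"
                if ":" in fields[6]:
                    sv_class = fields[6].rsplit(":", 1)[1]
            else:
                name = fields[6]
                sample, _, sv_class = name.partition(":")
                sv_class = sv_class or "unknown"
            if sv_class not in SV_CLASSES:
                sv_class = "unknown"
            bp1 = Breakpoint(c1, s1, sample, fields[8] if fields[8] in "+-" else "unknown")
            bp2 = Breakpoint(c2, s2, sample, fields[9] if fields[9] in "+-" else "unknown")
            rearrs.append(Rearrangement.canonical(bp1, bp2, sv_class, genome))
    if n_skipped:
        log.warning("read_bedpe: skipped %d records on unknown chromosomes", n_skipped)
    return rearrs


def write_bedpe(rearrs: list[Rearrangement], path) -> None:
    with open(path, "w") as fh:
        for r in rearrs:
            fh.write("\t".join(map(str, [
                r.bp1.chrom, r.bp1.pos, r.bp1.pos + 1,
                r.bp2.chrom, r.bp2.pos, r.bp2.pos + 1,
                f"{r.sample_id}:{r.sv_class}", ".",
                r.bp1.orientation if r.bp1.orientation in "+-" else ".",
                r.bp2.orientation if r.bp2.orientation in "+-" else ".",
            ])) + "\n")


_SIG_PREFIX = "sig_"


def read_mutations(path, one_based: bool = False) -> list[MutationRecord]:
    """Read a MAF-like headered TSV of SNVs and indels.

    Required columns: chrom, pos, ref, alt, sample_id.  Optional:
    in_mappable, in_palindrome (0/1) and any number of per-signature
    attribution columns named ``sig_<name>``.  Set ``one_based=True`` for
    tables using 1-based positions; conversion is explicit, never guessed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = {"chrom", "pos", "ref", "alt", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"mutation table missing columns: {sorted(missing)}")
    sig_cols = [c for c in df.columns if c.startswith(_SIG_PREFIX)]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ref, alt = str(d["ref"]), str(d["alt"])
        var_type, indel_len = MutationRecord.classify_alleles(ref, alt)
        sigs = tuple((c[len(_SIG_PREFIX):], float(d[c])) for c in sig_cols
                     if np.isfinite(d[c]))
        out.append(MutationRecord(
            chrom=str(d["chrom"]), pos=int(d["pos"]) - (1 if one_based else 0),
            ref=ref, alt=alt, sample_id=str(d["sample_id"]),
            var_type=var_type, indel_length=indel_len,
            signature_fractions=sigs,
            in_mappable=bool(d.get("in_mappable", 1)),
            in_palindrome=bool(d.get("in_palindrome", 0))))
    return out


def write_mutations(muts: list[MutationRecord], path) -> None:
    sig_names = sorted({n for m in muts for n, _ in m.signature_fractions})
    rows = []
    for m in muts:
        row = dict(chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                   sample_id=m.sample_id, in_mappable=int(m.in_mappable),
                   in_palindrome=int(m.in_palindrome))
        for n in sig_names:
            row[_SIG_PREFIX + n] = m.signature_fraction(n)
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "sample_id", "in_mappable",
            "in_palindrome"] + [_SIG_PREFIX + n for n in sig_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_elements(path, element_type: str = "custom") -> list[Element]:
    """Read BED4 element definitions, merging intervals that share an id."""
    by_id: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, line_no, "BED4 requires 4 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad coordinate: {exc}") from None
            by_id.setdefault(fields[3], []).append((chrom, start, end))
    return [Element(eid, ivals, element_type) for eid, ivals in by_id.items()]


def write_elements(elements: list[Element], path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            for chrom, start, end in el.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{el.id}\n")


def read_track(path, genome: GenomeDef, width: int, name: Optional[str] = None) -> CovariateTrack:
    """Read a bedGraph-like 4-column TSV into per-bin values.

    Input intervals are averaged into the ``width``-bp binning of
    ``genome``, weighting by overlap length; bins with no data are masked.
    """
    path = Path(path)
    bins = make_bins(genome, width)
    acc = np.zeros(len(bins))
    cov = np.zeros(len(bins))
    starts = {b.chrom: j for j, b in enumerate(bins) if b.start == 0}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, line_no, "bedGraph requires 4 columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in genome:
                continue
            s = max(0, s)
            e = min(e, genome.length_of(chrom))
            j0 = starts[chrom]
            for j in range(j0 + s // width, j0 + (e - 1) // width + 1):
                ov = min(e, bins[j].end) - max(s, bins[j].start)
                if ov > 0:
                    acc[j] += v * ov
                    cov[j] += ov
    mask = cov == 0
    values = np.where(mask, np.nan, acc / np.where(mask, 1.0, cov))
    return CovariateTrack(name or path.stem, values, mask)


def write_track(track: CovariateTrack, bins, path) -> None:
    with open(path, "w") as fh:
        for b, v, m in zip(bins, track.values, track.mask):
            if not m:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{v:.10g}\n")


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as headered TSV (round-trip stable)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
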