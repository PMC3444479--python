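"""mtDNA variants, heteroplasmy resolution, and haplotype collapsing.

A variant is a single change relative to a reference sequence, in 1-based
coordinates:

* SNV            -- ``m.263A>G``: single base substitution.
* insertion      -- ``m.303insCC`` (or ``m.303_304insCC``): bases inserted
                    *after* the anchor position.
* deletion       -- ``m.290_291del`` / ``m.290del``: closed interval removed.

Indels are left-normalised against the reference (shifted to the smallest
anchor/start that yields the same sequence), so that variant sets derived
from sequences are canonical and round-trip exactly. Each indel counts as a
single variant (one mutational step) regardless of length.

Heteroplasmic sites -- more than one allele observed within an individual --
are resolved to the majority allele, with ties going to the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .reference import ReferenceSequence

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

_NUC = frozenset("ACGTN")

_SNV_RE = re.compile(r"^m\.(\d+)([ACGTN])>([ACGTN])$")
_INS_RE = re.compile(r"^m\.(\d+)(?:_(\d+))?ins([ACGTN]+)$")
_DEL_RE = re.compile(r"^m\.(\d+)(?:_(\d+))?del([ACGTN]*)$")


class VariantError(ValueError):
    """Malformed token, out-of-range position, or reference mismatch."""


@dataclass(frozen=True)
class Variant:
    """One mtDNA change in 1-based reference coordinates.

    ``ref_allele`` is empty for insertions, ``alt_allele`` empty for
    deletions. The ``heteroplasmic`` flag records that a minor allele was
    observed at the site; it does not enter equality or hashing, so a
    heteroplasmic and a homoplasmic observation of the same change collapse
    to the same haplotype.
    """

    position: int
    kind: str
    ref_allele: str
    alt_allele: str
    heteroplasmic: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in (SNV, INSERTION, DELETION):
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise VariantError("ref and alt alleles are identical")
        if self.kind == SNV and not (len(self.ref_allele) == 1 and len(self.alt_allele) == 1):
            raise VariantError("SNV must have single-base ref and alt")
        if self.kind == INSERTION and (self.ref_allele or not self.alt_allele):
            raise VariantError("insertion has empty ref and non-empty alt")
        if self.kind == DELETION and (self.alt_allele or not self.ref_allele):
            raise VariantError("deletion has non-empty ref and empty alt")

    @property
    def end(self) -> int:
        """Last reference position affected (closed interval; = position for SNV/ins)."""
        if self.kind == DELETION:
            return self.position + len(self.ref_allele) - 1
        return self.position

    def token(self) -> str:
        if self.kind == SNV:
            return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"
        if self.kind == INSERTION:
            return f"m.{self.position}ins{self.alt_allele}"
        if len(self.ref_allele) == 1:
            return f"m.{self.position}del"
        return f"m.{self.position}_{self.end}del"

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"Variant({self.token()})"


@dataclass(frozen=True)
class Haplotype:
    """A distinct set of variants carried by zero or more subjects."""

    id: str
    variants: frozenset[Variant]
    carrier_count: int = 0
    observed: bool = True

    def __post_init__(self) -> None:
        if self.carrier_count < 0:
            raise ValueError("carrier_count must be non-negative")
        if self.carrier_count == 0 and self.observed:
            raise ValueError("observed haplotype must have carriers")
        seen: set[tuple[int, str]] = set()
        for v in self.variants:
            if v.kind in (SNV, DELETION):
                key = (v.position, "sub/del")
                if key in seen:
                    raise ValueError(f"haplotype {self.id}: two SNV/deletions at {v.position}")
                seen.add(key)


def validate_variant(v: Variant, reference: ReferenceSequence) -> None:
    """Check a variant against a loaded reference (bounds and ref alleles)."""
    if v.end > reference.length:
        raise VariantError(
            f"{v.token()}: position exceeds reference length {reference.length}"
        )
    if v.kind in (SNV, DELETION):
        expected = reference.slice(v.position, v.end)
        if v.ref_allele != expected:
            raise VariantError(
                f"{v.token()}: ref allele {v.ref_allele!r} does not match "
                f"reference {expected!r} at {v.position}"
            )


def normalize_variant(v: Variant, reference: ReferenceSequence) -> Variant:
    """Left-align an indel to its canonical position; SNVs pass through."""
    if v.kind == SNV:
        return v
    if v.kind == INSERTION:
        anchor, seq = v.position, v.alt_allele
        while anchor > 1 and seq[-1] == reference.base_at(anchor):
            seq = reference.base_at(anchor) + seq[:-1]
            anchor -= 1
        return Variant(anchor, INSERTION, "", seq, v.heteroplasmic)
    start, k = v.position, len(v.ref_allele)
    while start > 1 and reference.base_at(start - 1) == reference.base_at(start + k - 1):
        start -= 1
    return Variant(start, DELETION, reference.slice(start, start + k - 1), "", v.heteroplasmic)


def parse_variant_token(token: str, reference: ReferenceSequence) -> Variant:
    """Parse m-dot notation (``m.3915G>A``, ``m.303insC``, ``m.290_291del``).

    The returned variant is validated against the reference (SNV/deletion ref
    alleles must match) and indels are left-normalised.
    """
    token = token.strip()
    m = _SNV_RE.match(token)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        v = Variant(pos, SNV, ref, alt)
        validate_variant(v, reference)
        return v
    m = _INS_RE.match(token)
    if m:
        anchor = int(m.group(1))
        if m.group(2) is not None and int(m.group(2)) != anchor + 1:
            raise VariantError(f"{token}: insertion interval must be anchor_anchor+1")
        if not 1 <= anchor <= reference.length:
            raise VariantError(f"{token}: anchor outside reference")
        return normalize_variant(Variant(anchor, INSERTION, "", m.group(3)), reference)
    m = _DEL_RE.match(token)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) is not None else start
        if end < start:
            raise VariantError(f"{token}: deletion end before start")
        if end > reference.length or start < 1:
            raise VariantError(f"{token}: interval outside reference")
        ref_bases = reference.slice(start, end)
        if m.group(3) and m.group(3) != ref_bases:
            raise VariantError(f"{token}: deleted bases do not match reference {ref_bases!r}")
        return normalize_variant(Variant(start, DELETION, ref_bases, ""), reference)
    raise VariantError(f"unrecognised variant token {token!r}")


def resolve_heteroplasmy(
    calls: Sequence[tuple[str, float]], reference_allele: str | None = None
) -> str:
    """Majority allele at one site; ties resolve to the reference allele.

    ``calls`` are (allele, fraction) pairs with non-negative fractions summing
    to at most ~1. With a single call the allele is returned unchanged.
    """
    if not calls:
        raise VariantError("empty call list")
    total = 0.0
    for allele, frac in calls:
        if frac < 0:
            raise VariantError("negative allele fraction")
        total += frac
    if total > 1.0 + 1e-6:
        raise VariantError(f"allele fractions sum to {total} > 1")
    best = max(calls, key=lambda c: c[1])
    top = [allele for allele, frac in calls if frac >= best[1] - 1e-12]
    if len(top) > 1:
        if reference_allele is not None and reference_allele in top:
            return reference_allele
        return sorted(top)[0]
    return best[0]


def collapse_haplotypes(
    subject_variants: Mapping[str, Iterable[Variant]],
) -> tuple[list[Haplotype], dict[str, str]]:
    """Group subjects by identical variant sets.

    Returns the distinct haplotypes (ids ``H001``... ordered by descending
    carrier count, then token list) and the subject -> haplotype id map.
    Carrier counts sum to the number of subjects.
    """
    groups: dict[frozenset[Variant], list[str]] = {}
    for subject, variants in subject_variants.items():
        groups.setdefault(frozenset(variants), []).append(subject)
    keyed = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), tuple(sorted(v.token() for v in kv[0]))),
    )
    haplotypes: list[Haplotype] = []
    assignment: dict[str, str] = {}
    for i, (varset, subjects) in enumerate(keyed, start=1):
        hap_id = f"H{i:03d}"
        haplotypes.append(Haplotype(hap_id, varset, carrier_count=len(subjects)))
        for s in subjects:
            assignment[s] = hap_id
    return haplotypes, assignment


def sequence_from_variants(
    variants: Iterable[Variant], reference: ReferenceSequence
) -> str:
    """Apply a variant set to the reference. The empty set returns the reference."""
    variants = sorted(variants, key=lambda v: (v.position, v.kind))
    # overlap check over SNV/deletion footprints
    last_end = 0
    for v in variants:
        if v.kind == INSERTION:
            continue
        if v.position <= last_end:
            raise VariantError(f"overlapping variants at position {v.position}")
        last_end = v.end
    snv = {v.position: v for v in variants if v.kind == SNV}
    dele = {v.position: v for v in variants if v.kind == DELETION}
    ins = {}
    for v in variants:
        if v.kind == INSERTION:
            if v.position in ins:
                raise VariantError(f"two insertions anchored at {v.position}")
            ins[v.position] = v
    for v in dele.values():
        for a in range(v.position, v.end + 1):
            if a in ins and a != v.end:
                raise VariantError(f"insertion inside deleted interval at {a}")
    out: list[str] = []
    pos = 1
    while pos <= reference.length:
        if pos in dele:
            end = dele[pos].end
            if end in ins:
                out.append(ins[end].alt_allele)
            pos = end + 1
            continue
        out.append(snv[pos].alt_allele if pos in snv else reference.base_at(pos))
        if pos in ins:
            out.append(ins[pos].alt_allele)
        pos += 1
    return "".join(out)


def variants_from_sequences(sequence: str, reference: ReferenceSequence) -> frozenset[Variant]:
    """Derive the canonical (left-normalised) variant set turning reference into sequence.

    An optimal edit-distance alignment (edlib) locates the differences; runs
    of edits separated by fewer than five matched bases are re-canonicalised
    jointly (equally optimal alignments may split one indel into pieces), so
    isolated variants round-trip exactly through
    :func:`sequence_from_variants`.
    """
    import edlib

    if sequence == reference.bases:
        return frozenset()
    res = edlib.align(sequence, reference.bases, mode="NW", task="path")
    # collect per-op edit regions in (ref, alt) coordinates
    regions: list[list[int]] = []  # [ref_start, ref_end, alt_start, alt_end) 0-based
    ref_pos = alt_pos = 0
    for length_s, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length_s)
        if op in ("=", "M"):
            for k in range(length):
                if reference.bases[ref_pos + k] != sequence[alt_pos + k]:
                    regions.append([ref_pos + k, ref_pos + k + 1, alt_pos + k, alt_pos + k + 1])
            ref_pos += length
            alt_pos += length
        elif op == "X":
            regions.append([ref_pos, ref_pos + length, alt_pos, alt_pos + length])
            ref_pos += length
            alt_pos += length
        elif op == "I":
            regions.append([ref_pos, ref_pos, alt_pos, alt_pos + length])
            alt_pos += length
        else:  # D
            regions.append([ref_pos, ref_pos + length, alt_pos, alt_pos])
            ref_pos += length
    # merge regions separated by short match runs (alignment ambiguity)
    merged: list[list[int]] = []
    for reg in regions:
        if merged and reg[0] - merged[-1][1] < 5:
            merged[-1][1], merged[-1][3] = reg[1], reg[3]
        else:
            merged.append(reg)
    out: list[Variant] = []
    for rs, re_, as_, ae in merged:
        ref_sub = reference.bases[rs:re_]
        alt_sub = sequence[as_:ae]
        if len(ref_sub) == len(alt_sub):
            for k, (rb, ab) in enumerate(zip(ref_sub, alt_sub)):
                if rb != ab:
                    out.append(Variant(rs + k + 1, SNV, rb, ab))
            continue
        # single indel: trim common prefix and suffix
        lcp = 0
        while lcp < min(len(ref_sub), len(alt_sub)) and ref_sub[lcp] == alt_sub[lcp]:
            lcp += 1
        lcs = 0
        while (lcs < min(len(ref_sub), len(alt_sub)) - lcp
               and ref_sub[-1 - lcs] == alt_sub[-1 - lcs]):
            lcs += 1
        core_ref = ref_sub[lcp : len(ref_sub) - lcs]
        core_alt = alt_sub[lcp : len(alt_sub) - lcs]
        if core_ref and not core_alt:
            out.append(normalize_variant(
                Variant(rs + lcp + 1, DELETION, core_ref, ""), reference))
        elif core_alt and not core_ref:
            anchor = max(rs + lcp, 1)
            out.append(normalize_variant(
                Variant(anchor, INSERTION, "", core_alt), reference))
        else:
            # mixed cluster (e.g. SNV adjacent to indel): emit the indel for
            # the length difference plus SNVs for remaining mismatches
            if len(core_ref) > len(core_alt):
                k = len(core_ref) - len(core_alt)
                out.append(normalize_variant(
                    Variant(rs + lcp + 1, DELETION, core_ref[:k], ""), reference))
                tail_ref, tail_alt, offset = core_ref[k:], core_alt, rs + lcp + k
            else:
                k = len(core_alt) - len(core_ref)
                anchor = max(rs + lcp, 1)
                out.append(normalize_variant(
                    Variant(anchor, INSERTION, "", core_alt[:k]), reference))
                tail_ref, tail_alt, offset = core_ref, core_alt[k:], rs + lcp
            for j, (rb, ab) in enumerate(zip(tail_ref, tail_alt)):
                if rb != ab:
                    out.append(Variant(offset + j + 1, SNV, rb, ab))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = ["subject_id", "position", "ref", "alt", "het_fraction"]


def read_variant_table(
    path: Union[str, Path],
    reference: ReferenceSequence,
    exclude_windows: Sequence[tuple[int, int]] = (),
) -> dict[str, set[Variant]]:
    """Read a per-subject variant TSV and resolve heteroplasmy.

    Columns: subject_id, position, ref, alt, het_fraction (optional; fraction
    of the alt allele, blank = homoplasmic alt). ``-`` denotes the empty
    allele for indels. Sites whose alt fraction is <= 0.5 resolve to the
    reference and are dropped; fractions strictly between 0 and 1 mark the
    retained variant heteroplasmic. ``exclude_windows`` removes variants whose
    position falls in any closed window (e.g. poly-C tracts); default keeps
    everything.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "ref": str, "alt": str})
    if "het_fraction" not in df.columns:
        df["het_fraction"] = float("nan")
    subjects: dict[str, set[Variant]] = {}
    for row in df.itertuples(index=False):
        subjects.setdefault(row.subject_id, set())
        pos = int(row.position)
        ref = "" if row.ref in ("-", "", None) or pd.isna(row.ref) else str(row.ref).upper()
        alt = "" if row.alt in ("-", "", None) or pd.isna(row.alt) else str(row.alt).upper()
        frac = row.het_fraction
        heteroplasmic = False
        if not pd.isna(frac):
            frac = float(frac)
            ref_site_allele = ref if ref else reference.base_at(pos)
            keep = resolve_heteroplasmy([(alt, frac), (ref_site_allele, 1.0 - frac)],
                                        reference_allele=ref_site_allele)
            if keep != alt:
                continue  # majority is the reference allele: no variant retained
            heteroplasmic = 0.0 < frac < 1.0
        if any(lo <= pos <= hi for lo, hi in exclude_windows):
            continue
        if ref and alt:
            v = Variant(pos, SNV, ref, alt, heteroplasmic)
        elif alt:
            v = normalize_variant(Variant(pos, INSERTION, "", alt, heteroplasmic), reference)
        elif ref:
            v = normalize_variant(Variant(pos, DELETION, ref, "", heteroplasmic), reference)
        else:
            raise VariantError(f"row with empty ref and alt at position {pos}")
        validate_variant(v, reference)
        subjects[row.subject_id].add(v)
    return subjects


def write_variant_table(
    path: Union[str, Path],
    subject_variants: Mapping[str, Iterable[Variant]],
    het_fractions: Mapping[tuple[str, Variant], float] | None = None,
) -> None:
    """Write per-subject variants as TSV (inverse of :func:`read_variant_table`)."""
    rows = []
    for subject in sorted(subject_variants):
        for v in sorted(subject_variants[subject], key=lambda v: (v.position, v.kind, v.alt_allele)):
            frac = ""
            if het_fractions is not None and (subject, v) in het_fractions:
                frac = f"{het_fractions[(subject, v)]:.4f}"
            rows.append(
                (subject, v.position, v.ref_allele or "-", v.alt_allele or "-", frac)
            )
    df = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
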