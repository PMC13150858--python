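"""Fingerprint encodings for genotype profiles over a marker panel.

Three textual representations of an accession's ordered calls:

* slash string — one ``X/Y`` token per locus ("C/T G/A ..."), alleles
  ordered ref-then-alt for heterozygotes, ``-/-`` for missing;
* compact string — one character per locus: the base for homozygotes, the
  IUPAC ambiguity code for heterozygotes (R=A/G, Y=C/T, S=C/G, W=A/T,
  K=G/T, M=A/C), ``N`` for missing;
* category vector — MISS / Ref / Het_Alt / Hom_Alt per locus, the states
  of the fingerprint heat-map matrix.

The QR payload is the plain text ``Name: <name>; fingerprint code:
<slash string>`` — the contract is the payload text, not an image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix

CATEGORIES = ("MISS", "Ref", "Het_Alt", "Hom_Alt")

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
IUPAC_REVERSE = {v: k for k, v in IUPAC.items()}


@dataclass
class FingerprintProfile:
    """One accession's fingerprint over an ordered marker panel."""

    accession: str
    display_name: str
    calls: np.ndarray               # dosages over panel loci, -1 missing
    ref: list[str]
    alt: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not (len(self.ref) == len(self.alt) == self.calls.size):
            raise ValueError("calls and panel allele lists disagree in length")

    @property
    def slash_string(self) -> str:
        return encode_slash_string(self.calls, self.ref, self.alt)

    @property
    def compact_string(self) -> str:
        return encode_compact_string(self.calls, self.ref, self.alt)

    @property
    def categories(self) -> list[str]:
        return categorize(self.calls)


def _token(dosage: int, ref: str, alt: str) -> str:
    if dosage == MISSING:
        return "-/-"
    if dosage == 0:
        return f"{ref}/{ref}"
    if dosage == 1:
        return f"{ref}/{alt}"
    if dosage == 2:
        return f"{alt}/{alt}"
    raise ValueError(f"invalid dosage {dosage}")


def encode_slash_string(calls, ref: list[str], alt: list[str]) -> str:
    """Space-separated ``X/Y`` token per locus; het as ref/alt, missing -/-."""
    return " ".join(
        _token(int(d), r, a) for d, r, a in zip(np.asarray(calls), ref, alt)
    )


def parse_slash_string(text: str, ref: list[str], alt: list[str]) -> np.ndarray:
    """Invert :func:`encode_slash_string` back to a dosage vector."""
    tokens = text.split()
    if len(tokens) != len(ref):
        raise ValueError(f"{len(tokens)} tokens for a {len(ref)}-locus panel")
    calls = np.empty(len(tokens), dtype=np.int8)
    for i, (tok, r, a) in enumerate(zip(tokens, ref, alt)):
        alleles = tok.split("/")
        if alleles == ["-", "-"]:
            calls[i] = MISSING
        elif alleles == [r, r]:
            calls[i] = 0
        elif sorted(alleles) == sorted([r, a]):
            calls[i] = 1
        elif alleles == [a, a]:
            calls[i] = 2
        else:
            raise ValueError(f"token {tok!r} incompatible with alleles {r}/{a}")
    return calls


def encode_compact_string(calls, ref: list[str], alt: list[str]) -> str:
    """One character per locus: base, IUPAC ambiguity code, or N."""
    out = []
    for d, r, a in zip(np.asarray(calls), ref, alt):
        d = int(d)
        if d == MISSING:
            out.append("N")
        elif d == 0:
            out.append(r)
        elif d == 2:
            out.append(a)
        elif d == 1:
            out.append(IUPAC[frozenset((r, a))])
        else:
            raise ValueError(f"invalid dosage {d}")
    return "".join(out)


def categorize(calls) -> list[str]:
    """Map dosages to MISS / Ref / Het_Alt / Hom_Alt category labels."""
    mapping = {MISSING: "MISS", 0: "Ref", 1: "Het_Alt", 2: "Hom_Alt"}
    return [mapping[int(d)] for d in np.asarray(calls)]


def qr_payload(profile: FingerprintProfile) -> str:
    """Byte-stable QR text: name plus the full slash-string fingerprint."""
    return f"Name: {profile.display_name}; fingerprint code: {profile.slash_string}"


def profiles_from_matrix(
    matrix: GenotypeMatrix, panel_indices=None,
    display_names: dict[str, str] | None = None,
) -> list[FingerprintProfile]:
    """Build one profile per accession over the given panel loci."""
    m = matrix if panel_indices is None else matrix.take_loci(
        np.asarray(panel_indices))
    ref = [str(b) for b in m.ref]
    alt = [str(b) for b in m.alt]
    display_names = display_names or {}
    return [
        FingerprintProfile(
            accession=acc,
            display_name=display_names.get(acc, acc),
            calls=m.genotypes[i], ref=ref, alt=alt,
        )
        for i, acc in enumerate(m.accessions)
    ]


def fingerprint_matrix(profiles: list[FingerprintProfile]):
    """Category matrix: rows = panel loci, columns = accessions."""
    import pandas as pd

    return pd.DataFrame(
        {p.accession: p.categories for p in profiles},
    )


def verify_uniqueness(profiles: list[FingerprintProfile]) -> dict:
    """Find duplicate and ambiguous fingerprint groups.

    Confirmed duplicates share an identical compact string. Pairs that
    differ only at loci where at least one is missing (N treated as a
    wildcard) are reported separately as ambiguous matches.
    """
    if not profiles:
        raise ValueError("no profiles to check")
    by_string: dict[str, list[str]] = {}
    for p in profiles:
        by_string.setdefault(p.compact_string, []).append(p.accession)
    duplicates = [sorted(v) for v in by_string.values() if len(v) > 1]

    ambiguous = []
    strings = [(p.accession, p.compact_string) for p in profiles]
    for i in range(len(strings)):
        for j in range(i + 1, len(strings)):
            a, sa = strings[i]
            b, sb = strings[j]
            if sa == sb:
                continue
            if all(x == y or x == "N" or y == "N" for x, y in zip(sa, sb)):
                ambiguous.append((a, b))
    return {"duplicates": sorted(duplicates), "ambiguous": sorted(ambiguous)}
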