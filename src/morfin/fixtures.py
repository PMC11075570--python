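"""Synthetic-data generators and the packaged EF-4 insertion-site map.

Everything here is deterministic under an explicit seed and self-contained:
no accession downloads.  Synthetic plasmids emulate the geometry of the
expression vectors used for transposition targets (a circular backbone
carrying one annotated ORF); synthetic FP ORFs are stop-free random coding
sequences, optionally carrying the real 5'/3' termini of GFPmut3,
mCherry2 or mYPET (as implied by the published primer sequences) so that
primer designs can be checked byte-for-byte without bundling full FP
genes.

The packaged site map records insertion-site recovery counts for the
E. coli elongation factor EF-4 target accumulated over 159 student
transposition experiments.  Only sites whose recovery counts were
published as text are included — counts read off a figure are not used as
ground truth — so the map is an enumerated subset, and the experiment
total is stored as metadata, not an invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .seq_core import OrfAnnotation, ParameterError, ParseError, PlasmidRecord, revcomp, translate

__all__ = [
    "synth_plasmid",
    "synth_fp_orf",
    "FpTerminus",
    "FP_TERMINI",
    "synth_fp_with_termini",
    "SiteMap",
    "load_ef4_site_map",
    "read_site_map",
    "write_site_map",
    "domain_report",
]

_BASES = np.array(list("ACGT"))
# all 61 sense codons of the bacterial code
_SENSE_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
)


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    """ATG + random sense codons + TAA, ``orf_len`` nt total."""
    interior = orf_len // 3 - 2
    codons = rng.choice(_SENSE_CODONS, size=interior)
    return "ATG" + "".join(codons) + "TAA"


def synth_plasmid(
    seed: int,
    backbone_len: int = 4728,
    orf_len: int = 2109,
    label: str = "target_orf",
    strand: str = "+",
) -> PlasmidRecord:
    """A circular plasmid of ``backbone_len + orf_len`` bp with one ORF.

    Defaults reproduce the worked-example geometry: a 2,109 bp target ORF
    on a 6,837 bp plasmid.  The ORF (ATG start, stop-free interior, single
    terminal stop) is placed mid-backbone on the requested strand.
    """
    if orf_len % 3 or orf_len < 30:
        raise ParameterError(f"orf_len must be a multiple of 3 >= 30, got {orf_len}")
    if backbone_len < 0:
        raise ParameterError(f"backbone_len must be >= 0, got {backbone_len}")
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(_BASES, size=backbone_len))
    orf = _random_orf(rng, orf_len)
    pos = backbone_len // 2
    inserted = orf if strand == "+" else revcomp(orf)
    sequence = backbone[:pos] + inserted + backbone[pos:]
    return PlasmidRecord(
        name=f"synth_plasmid_s{seed}",
        sequence=sequence,
        circular=True,
        orfs=[OrfAnnotation(label, pos, pos + orf_len, strand)],
    )


def synth_fp_orf(seed: int, aa_len: int = 238) -> str:
    """A synthetic FP-like ORF: ATG + ``aa_len`` sense codons + TAA
    (``3 * (aa_len + 2)`` nt)."""
    if aa_len < 10:
        raise ParameterError(f"aa_len must be >= 10, got {aa_len}")
    rng = np.random.default_rng(seed)
    return _random_orf(rng, 3 * (aa_len + 2))


@dataclass(frozen=True)
class FpTerminus:
    """Published 5'/3' termini of a real FP ORF, with the annealing lengths
    that reproduce the published primer pairs."""

    name: str
    five_prime: str  # starts with ATG
    three_prime: str  # sense strand, includes the stop codon
    anneal_fwd: int  # FP-derived bases in the forward primer (incl. the 2 start-codon bases)
    anneal_rev: int  # FP sense bases upstream of the ablated stop in the reverse primer


FP_TERMINI: dict[str, FpTerminus] = {
    t.name: t
    for t in (
        FpTerminus(
            "GFPmut3",
            "ATGAGTAAAGGAGAAGAAC",
            "GATGAACTATACAAATAA",
            anneal_fwd=18,
            anneal_rev=15,
        ),
        FpTerminus(
            "mCherry2",
            "ATGGTGAGCAAGGGCG",
            "GGACGAGCTGTACAAGTAA",
            anneal_fwd=15,
            anneal_rev=16,
        ),
        FpTerminus(
            "mYPET",
            "ATGTCTAAAGGTGAAGAATTATTCACTGG",
            "CCGAGGGTATGAATGAATTGTACAAATAA",
            anneal_fwd=28,
            anneal_rev=26,
        ),
    )
}


def synth_fp_with_termini(name: str, seed: int = 0, total_codons: int = 240) -> str:
    """A full-length synthetic FP ORF carrying the real termini of ``name``.

    The interior is random stop-free coding sequence; only the published
    termini are real, which is all the primer designer reads.
    """
    if name not in FP_TERMINI:
        raise ParameterError(f"unknown FP {name!r}; choose from {sorted(FP_TERMINI)}")
    t = FP_TERMINI[name]
    five, three = t.five_prime, t.three_prime
    need = 3 * total_codons - len(five) - len(three)
    if need < 3:
        raise ParameterError(f"total_codons={total_codons} too small for the termini")
    rng = np.random.default_rng(seed)
    stops = ("TAA", "TAG", "TGA")
    # complete the codon the 5' terminus ends inside, avoiding a stop
    r5 = len(five) % 3
    pad5 = ""
    if r5:
        while True:
            pad5 = "".join(rng.choice(_BASES, size=3 - r5))
            if five[-r5:] + pad5 not in stops:
                break
    # and the codon the 3' terminus starts inside
    r3 = len(three) % 3
    pad3 = ""
    if r3:
        while True:
            pad3 = "".join(rng.choice(_BASES, size=3 - r3))
            if pad3 + three[:r3] not in stops:
                break
    n_codons = (need - len(pad5) - len(pad3)) // 3
    if n_codons < 0:
        raise ParameterError(f"total_codons={total_codons} too small for the termini")
    mid = pad5 + "".join(rng.choice(_SENSE_CODONS, size=n_codons)) + pad3
    orf = five + mid + three
    assert len(orf) % 3 == 0
    pep = translate(orf)
    assert pep.endswith("*") and "*" not in pep[:-1], "terminus junction made a stop"
    return orf


# ---------------------------------------------------------------------------
# EF-4 site map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMap:
    """Insertion-site recovery counts with the target's domain intervals."""

    target_label: str
    sites: dict[int, int]
    domains: tuple[tuple[str, int, int], ...]  # (label, start aa, end aa) inclusive
    total_experiments: int = 0
    target_length: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        for codon, count in self.sites.items():
            if count <= 0:
                raise ParameterError(f"site {codon}: count must be positive")
            if self.target_length and not 1 <= codon <= self.target_length:
                raise ParameterError(
                    f"site {codon} outside target of {self.target_length} codons"
                )

    @property
    def modal_site(self) -> tuple[int, int]:
        """(codon, count) of the most frequently recovered site."""
        codon = max(self.sites, key=lambda c: (self.sites[c], -c))
        return codon, self.sites[codon]

    @property
    def total_recoveries(self) -> int:
        return sum(self.sites.values())


def _data_path(name: str):
    return resources.files("morfin.data").joinpath(name)


def load_ef4_site_map() -> SiteMap:
    """The packaged EF-4 (599-codon) map: published cluster counts and the
    five domain intervals."""
    with resources.as_file(_data_path("ef4_site_map.tsv")) as path:
        return read_site_map(path)


def read_site_map(path: str | Path) -> SiteMap:
    """Parse the site-map format: a ``---``-delimited YAML header followed
    by TSV lines ``codon<TAB>count``."""
    text = Path(path).read_text()
    parts = text.split("---\n")
    if len(parts) < 3:
        raise ParseError(f"{path}: expected a '---'-delimited YAML header")
    meta = yaml.safe_load(parts[1])
    body = parts[2]
    sites: dict[int, int] = {}
    for lineno, line in enumerate(body.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("codon"):
            continue
        try:
            codon_s, count_s = line.split("\t")
            sites[int(codon_s)] = int(count_s)
        except ValueError as exc:
            raise ParseError(f"{path}: bad TSV line {lineno}: {line!r}") from exc
    domains = tuple(
        (d["label"], int(d["start"]), int(d["end"])) for d in meta.get("domains", [])
    )
    return SiteMap(
        target_label=meta["target"],
        sites=sites,
        domains=domains,
        total_experiments=int(meta.get("total_experiments", 0)),
        target_length=int(meta.get("target_length_codons", 0)),
        provenance=str(meta.get("provenance", "")),
    )


def write_site_map(site_map: SiteMap, path: str | Path) -> None:
    meta = {
        "target": site_map.target_label,
        "target_length_codons": site_map.target_length,
        "total_experiments": site_map.total_experiments,
        "provenance": site_map.provenance,
        "domains": [
            {"label": label, "start": start, "end": end}
            for label, start, end in site_map.domains
        ],
    }
    lines = ["---", yaml.safe_dump(meta, sort_keys=False).rstrip(), "---", "codon\tcount"]
    lines += [f"{codon}\t{count}" for codon, count in sorted(site_map.sites.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def domain_report(site_map: SiteMap) -> dict[str, int]:
    """Recovery counts summed per domain interval; codons falling in
    inter-domain gaps are reported under ``interdomain``.  Totals conserve:
    the sum over the report equals the sum of all site counts."""
    report = {label: 0 for label, _, _ in site_map.domains}
    report["interdomain"] = 0
    for codon, count in site_map.sites.items():
        for label, start, end in site_map.domains:
            if start <= codon <= end:
                report[label] += count
                break
        else:
            report["interdomain"] += count
    return report
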