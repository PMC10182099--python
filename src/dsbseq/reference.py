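"""Synthetic recipient/donor reference genome for HO-break repair assays.

This module builds a small two-locus recombination reference in the style of
the PMV strain of *S. cerevisiae*: a recipient chromosome carrying a cleavable
HO recognition site inside a MATa-like locus, and a donor chromosome carrying
a homologous MATa'-like insert around an uncleavable HO-inc site.  The donor
insert differs from the recipient locus at a fixed set of single-nucleotide
polymorphisms (a subset of which create EcoRI sites), so that an exact-match
read carrying a donor allele can never align to the recipient chromosome and
vice versa.  The module also performs in-silico restriction digestion, which
is how the classic Southern-blot band sizes of the assay are validated.

All coordinates are 0-based, half-open.  Only file writers emit 1-based
coordinates where a format requires them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeConfig",
    "GenomeMap",
    "PolymorphicSite",
    "Fragment",
    "build_reference",
    "in_silico_digest",
    "fragment_for_probe",
    "write_reference",
    "read_reference",
    "HO_MOTIF",
    "HO_INC_MOTIF",
    "ECORI_MOTIF",
]

ECORI_MOTIF = "GAATTC"
# EcoRI cleaves between G and A; the cut coordinate of a motif starting at
# position m is therefore m + 1.
ECORI_CUT_OFFSET = 1

# 24-nt HO recognition core.  The cut coordinate sits at motif index 12, so a
# motif pasted at [ho - 12, ho + 12) is cleaved exactly at ``ho``.  The
# uncleavable HO-inc variant differs at motif index 11 (coordinate ho - 1).
HO_MOTIF = "TTTCAGCTTTCCGCAACAGTATAA"
HO_INC_MOTIF = HO_MOTIF[:11] + "A" + HO_MOTIF[12:]
HO_CUT_INDEX = 12
HO_INC_DIFF_INDEX = 11

_COMP = str.maketrans("ACGTN", "TGCAN")

# deterministic transversion used for non-EcoRI donor alleles
_ALLELE_SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PolymorphicSite:
    """One recipient/donor single-nucleotide difference in the homology arms."""

    recipient_pos: int
    donor_pos: int
    recipient_allele: str
    donor_allele: str
    creates_ecori: bool
    offset_from_ho: int

    def __post_init__(self):
        if self.recipient_allele == self.donor_allele:
            raise ValueError("polymorphism must change the base")


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment in half-open coordinates."""

    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("fragment must have positive length")


@dataclass
class GenomeConfig:
    """Geometry of the synthetic reference.

    Defaults encode the assay layout: a 1300-nt donor insert made of two
    638-nt homology arms flanking a 24-nt HO-inc core, 23 polymorphisms
    (12 left / 11 right of the cut, ~60-nt spacing), three of which create
    EcoRI sites on the donor, and recipient EcoRI sites at -2500/+4300 nt
    from the HO cut so that the uncut locus fragment is 6.8 kb and the
    left cut product 2.5 kb.
    """

    recipient_name: str = "chrIII"
    recipient_length: int = 60_000
    ho_site: int = 35_000
    donor_name: str = "chrV"
    donor_length: int = 40_000
    donor_insert_start: int = 5_000
    extra_chromosomes: dict = field(default_factory=lambda: {"chrVIII": 15_000})
    arm_length: int = 638
    polymorphism_spacing: int = 55
    first_offset: int = 30
    n_left: int = 12
    n_right: int = 11
    ecori_offsets: tuple = (-415, -85, 305)
    # EcoRI *cut* coordinates on the recipient, relative to ho_site
    recipient_ecori_offsets: tuple = (-2500, 4300)
    control_region: tuple = ("chrV", 15_000, 35_000)
    # resection-blocking elements (LTR analogue): offsets from ho_site
    block_offsets: tuple = ((-32_000, "LTR-delta"),)

    def polymorphism_offsets(self) -> list[int]:
        left = [-(self.first_offset + k * self.polymorphism_spacing) for k in range(self.n_left)]
        right = [self.first_offset + k * self.polymorphism_spacing for k in range(self.n_right)]
        return sorted(left) + right

    def validate(self) -> None:
        if self.arm_length <= self.polymorphism_spacing:
            raise ValueError("homology arm shorter than polymorphism spacing")
        if min(self.recipient_length, self.donor_length) <= 0:
            raise ValueError("chromosome lengths must be positive")
        half_core = HO_CUT_INDEX
        offs = self.polymorphism_offsets()
        if -min(offs) > self.arm_length + half_core or max(offs) >= self.arm_length + half_core:
            raise ValueError("polymorphisms fall outside the homology arms")
        if any(abs(o) < half_core for o in offs):
            raise ValueError("polymorphism placed inside the HO recognition core")
        for off in self.ecori_offsets:
            if off not in offs:
                raise ValueError(f"EcoRI-creating offset {off} is not a polymorphism offset")
        for cut in self.recipient_ecori_offsets:
            if abs(cut) <= self.arm_length + half_core:
                raise ValueError(
                    "recipient EcoRI site collides with the homology arms; the "
                    "polymorphic locus must not be interrupted by it"
                )
        chrom, s, e = self.control_region
        if chrom == self.donor_name:
            ins_end = self.donor_insert_start + 2 * self.arm_length + len(HO_MOTIF)
            if s < ins_end and self.donor_insert_start < e:
                raise ValueError("control region overlaps the donor insert")


@dataclass
class GenomeMap:
    """The assembled reference plus every annotated functional site."""

    chromosomes: dict  # name -> str sequence
    ho_site: int
    ho_inc_site: int
    recipient_name: str
    donor_name: str
    polymorphisms: list  # of PolymorphicSite
    restriction_sites: dict  # enzyme -> {chrom: sorted cut coords}
    control_region: tuple  # (chrom, start, end)
    donor_region: tuple
    homology_arms: dict  # side -> {"recipient": (s, e), "donor": (s, e)}
    block_elements: list  # of (chrom, position, label)
    config: GenomeConfig | None = None

    @property
    def chromosome_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def donor_to_recipient(self, donor_pos: int) -> int | None:
        """Map a donor-chromosome coordinate into the recipient (break-centred)
        frame via the homology arms; None if outside the donor insert."""
        s, e = self.donor_region[1], self.donor_region[2]
        if not (s <= donor_pos < e):
            return None
        return self.ho_site + (donor_pos - self.ho_inc_site)

    def sites_in_tract(self, left_offset: int, right_offset: int) -> list:
        return [p for p in self.polymorphisms if left_offset <= p.offset_from_ho <= right_offset]


def _scrub_motif(arr: np.ndarray, motif: str, rng: np.random.Generator,
                 keep: set[int] | None = None) -> None:
    """Mutate the third base of any occurrence of ``motif`` not in ``keep``.

    Works in place on a byte array; loops until no spurious occurrence is left
    so that pasted edits cannot recreate the motif at an unintended position.
    """
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    keep = keep or set()
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(50):
        hits = _find_motif(arr, m)
        bad = [h for h in hits if h not in keep]
        if not bad:
            return
        for h in bad:
            choices = alphabet[alphabet != arr[h + 2]]
            arr[h + 2] = rng.choice(choices)
    raise RuntimeError("could not scrub spurious restriction motifs")


def _find_motif(arr: np.ndarray, m: np.ndarray) -> list[int]:
    if len(arr) < len(m):
        return []
    win = np.lib.stride_tricks.sliding_window_view(arr, len(m))
    return list(np.nonzero((win == m).all(axis=1))[0])


def _random_chromosome(length: int, rng: np.random.Generator) -> np.ndarray:
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    _scrub_motif(arr, ECORI_MOTIF, rng)
    return arr


def build_reference(config: GenomeConfig | None = None, seed: int = 0) -> GenomeMap:
    """Assemble the synthetic reference genome.

    Deterministic for a given (config, seed).  The recipient chromosome gets
    the cleavable HO motif and its flanking EcoRI sites; the donor chromosome
    receives a copy of the recipient homology arms with the configured
    polymorphisms applied around the uncleavable HO-inc core.  Background
    sequence is i.i.d. uniform with every spurious EcoRI motif scrubbed, so
    restriction maps contain exactly the designed sites and 75-mers are
    unique outside the engineered homology.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD5B]))

    half = HO_CUT_INDEX  # 12 nt of HO core on each side of the cut
    ho = config.ho_site

    recipient = _random_chromosome(config.recipient_length, rng)
    # paste the HO core
    recipient[ho - half: ho + half] = np.frombuffer(HO_MOTIF.encode(), dtype=np.uint8)

    # recipient EcoRI sites at the configured cut offsets
    ecori_keep = set()
    for cut in config.recipient_ecori_offsets:
        start = ho + cut - ECORI_CUT_OFFSET
        recipient[start: start + 6] = np.frombuffer(ECORI_MOTIF.encode(), dtype=np.uint8)
        ecori_keep.add(start)

    # engineer recipient context of EcoRI-creating polymorphisms: GA x TTC
    # where the donor allele 'A' at x completes GAATTC and the recipient
    # allele 'C' does not.
    for off in config.ecori_offsets:
        p = ho + off
        recipient[p - 2: p + 4] = np.frombuffer(b"GACTTC", dtype=np.uint8)

    _scrub_motif(recipient, ECORI_MOTIF, rng, keep=ecori_keep)
    # scrubbing must not have touched the engineered features
    assert bytes(recipient[ho - half: ho + half]) == HO_MOTIF.encode()
    for off in config.ecori_offsets:
        assert bytes(recipient[ho + off - 2: ho + off + 4]) == b"GACTTC"

    # polymorphic sites and donor arms
    sites: list[PolymorphicSite] = []
    donor_insert = np.empty(2 * config.arm_length + len(HO_MOTIF), dtype=np.uint8)
    left_rec = recipient[ho - half - config.arm_length: ho - half].copy()
    right_rec = recipient[ho + half: ho + half + config.arm_length].copy()
    donor_start = config.donor_insert_start
    ho_inc = donor_start + config.arm_length + HO_CUT_INDEX

    for off in config.polymorphism_offsets():
        rpos = ho + off
        dpos = ho_inc + off
        r_allele = chr(recipient[rpos])
        if off in config.ecori_offsets:
            d_allele = "A"
            creates = True
        else:
            d_allele = _ALLELE_SWAP[r_allele]
            creates = False
        arm = left_rec if off < 0 else right_rec
        idx = off + half + config.arm_length if off < 0 else off - half
        assert chr(arm[idx]) == r_allele
        arm[idx] = ord(d_allele)
        sites.append(
            PolymorphicSite(
                recipient_pos=rpos,
                donor_pos=dpos,
                recipient_allele=r_allele,
                donor_allele=d_allele,
                creates_ecori=creates,
                offset_from_ho=off,
            )
        )

    donor_insert[: config.arm_length] = left_rec
    donor_insert[config.arm_length: config.arm_length + len(HO_MOTIF)] = np.frombuffer(
        HO_INC_MOTIF.encode(), dtype=np.uint8
    )
    donor_insert[config.arm_length + len(HO_MOTIF):] = right_rec

    donor = _random_chromosome(config.donor_length, rng)
    donor[donor_start: donor_start + len(donor_insert)] = donor_insert
    # donor EcoRI motifs start two bases left of the polymorphic position
    donor_keep = {ho_inc + off - 2 for off in config.ecori_offsets}
    _scrub_motif(donor, ECORI_MOTIF, rng, keep=donor_keep)
    # scrubbing must never touch the engineered insert
    assert bytes(donor[donor_start: donor_start + len(donor_insert)]) == bytes(donor_insert)

    chromosomes = {
        config.recipient_name: recipient.tobytes().decode(),
        config.donor_name: donor.tobytes().decode(),
    }
    for name, length in config.extra_chromosomes.items():
        chromosomes[name] = _random_chromosome(length, rng).tobytes().decode()

    genome = GenomeMap(
        chromosomes=chromosomes,
        ho_site=ho,
        ho_inc_site=ho_inc,
        recipient_name=config.recipient_name,
        donor_name=config.donor_name,
        polymorphisms=sites,
        restriction_sites={"EcoRI": _scan_restriction(chromosomes)},
        control_region=config.control_region,
        donor_region=(config.donor_name, donor_start, donor_start + len(donor_insert)),
        homology_arms={
            "left": {
                "recipient": (ho - half - config.arm_length, ho - half),
                "donor": (donor_start, donor_start + config.arm_length),
            },
            "right": {
                "recipient": (ho + half, ho + half + config.arm_length),
                "donor": (
                    donor_start + config.arm_length + len(HO_MOTIF),
                    donor_start + len(donor_insert),
                ),
            },
        },
        block_elements=[
            (config.recipient_name, ho + off, label) for off, label in config.block_offsets
        ],
        config=config,
    )
    _check_genome(genome)
    return genome


def _scan_restriction(chromosomes: dict) -> dict:
    sites = {}
    for name, seq in chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hits = _find_motif(arr, np.frombuffer(ECORI_MOTIF.encode(), dtype=np.uint8))
        sites[name] = sorted(h + ECORI_CUT_OFFSET for h in hits)
    return sites


def _check_genome(genome: GenomeMap) -> None:
    rec = genome.chromosomes[genome.recipient_name]
    don = genome.chromosomes[genome.donor_name]
    for p in genome.polymorphisms:
        assert rec[p.recipient_pos] == p.recipient_allele
        assert don[p.donor_pos] == p.donor_allele
    for chrom, cuts in genome.restriction_sites["EcoRI"].items():
        assert cuts == sorted(cuts)
        assert all(0 < c < len(genome.chromosomes[chrom]) for c in cuts)


def in_silico_digest(genome: GenomeMap, enzyme: str, extra_cuts: list | None = None) -> list:
    """Partition every chromosome at the enzyme's cut sites plus extra cuts.

    ``extra_cuts`` is a list of (chromosome, coordinate) pairs, e.g. the HO
    cut itself.  Fragments tile each chromosome exactly.
    """
    if enzyme not in genome.restriction_sites:
        raise KeyError(f"unknown enzyme: {enzyme}")
    cuts_by_chrom = {c: list(v) for c, v in genome.restriction_sites[enzyme].items()}
    for chrom, pos in extra_cuts or []:
        if chrom not in genome.chromosomes:
            raise KeyError(f"unknown chromosome: {chrom}")
        if not 0 < pos < len(genome.chromosomes[chrom]):
            raise ValueError("extra cut out of bounds")
        cuts_by_chrom.setdefault(chrom, []).append(pos)
    fragments = []
    for chrom, seq in genome.chromosomes.items():
        cuts = sorted(set(cuts_by_chrom.get(chrom, [])))
        bounds = [0] + cuts + [len(seq)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            fragments.append(Fragment(chrom, s, e))
    return fragments


def fragment_for_probe(fragments: list, probe: tuple) -> Fragment:
    """Return the unique fragment fully containing the probe interval.

    ``probe`` is (chromosome, start, end), half-open; start-inclusive, so a
    zero-length probe at a fragment start belongs to that fragment.  A probe
    spanning a cut is an error.
    """
    chrom, start, end = probe
    for frag in fragments:
        if frag.chromosome != chrom:
            continue
        if frag.start <= start and end <= frag.end:
            if start < frag.end:  # zero-length probes at a cut go rightwards
                return frag
    raise ValueError("probe spans a restriction cut or lies outside the digest")


# ---------------------------------------------------------------------------
# FASTA + site-annotation round trip

def write_reference(genome: GenomeMap, fasta_path, sites_path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    lines = ["#chrom\tstart\tend\tlabel\tattrs"]
    rec, don = genome.recipient_name, genome.donor_name
    lines.append(f"{rec}\t{genome.ho_site}\t{genome.ho_site}\tho_site\t.")
    lines.append(f"{don}\t{genome.ho_inc_site}\t{genome.ho_inc_site}\tho_inc_site\t.")
    for i, p in enumerate(genome.polymorphisms):
        attrs = (
            f"donor_pos={p.donor_pos};recipient_allele={p.recipient_allele};"
            f"donor_allele={p.donor_allele};creates_ecori={int(p.creates_ecori)};"
            f"offset={p.offset_from_ho}"
        )
        lines.append(f"{rec}\t{p.recipient_pos}\t{p.recipient_pos + 1}\tpolymorphism_{i}\t{attrs}")
    c, s, e = genome.control_region
    lines.append(f"{c}\t{s}\t{e}\tcontrol_region\t.")
    c, s, e = genome.donor_region
    lines.append(f"{c}\t{s}\t{e}\tdonor_region\t.")
    for side, arms in genome.homology_arms.items():
        for role, (s, e) in arms.items():
            chrom = rec if role == "recipient" else don
            lines.append(f"{chrom}\t{s}\t{e}\tarm_{side}_{role}\t.")
    for chrom, pos, label in genome.block_elements:
        lines.append(f"{chrom}\t{pos}\t{pos}\tblock_element\tlabel={label}")
    Path(sites_path).write_text("\n".join(lines) + "\n")


def read_reference(fasta_path, sites_path) -> GenomeMap:
    """Load a reference FASTA plus its site annotation (round-trips
    :func:`write_reference`; also the entry point for an externally supplied
    reference with a user-provided annotation in the same format)."""
    chromosomes = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    ho_site = ho_inc_site = None
    recipient_name = donor_name = None
    polymorphisms, blocks = [], []
    control_region = donor_region = None
    arms: dict = {"left": {}, "right": {}}
    for line in Path(sites_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, label, attrs = line.split("\t")
        start, end = int(start), int(end)
        kv = dict(a.split("=", 1) for a in attrs.split(";")) if attrs != "." else {}
        if label == "ho_site":
            ho_site, recipient_name = start, chrom
        elif label == "ho_inc_site":
            ho_inc_site, donor_name = start, chrom
        elif label.startswith("polymorphism"):
            polymorphisms.append(
                PolymorphicSite(
                    recipient_pos=start,
                    donor_pos=int(kv["donor_pos"]),
                    recipient_allele=kv["recipient_allele"],
                    donor_allele=kv["donor_allele"],
                    creates_ecori=bool(int(kv["creates_ecori"])),
                    offset_from_ho=int(kv["offset"]),
                )
            )
        elif label == "control_region":
            control_region = (chrom, start, end)
        elif label == "donor_region":
            donor_region = (chrom, start, end)
        elif label.startswith("arm_"):
            _, side, role = label.split("_")
            arms[side][role] = (start, end)
        elif label == "block_element":
            blocks.append((chrom, start, kv.get("label", "block")))
    if ho_site is None or ho_inc_site is None:
        raise ValueError("site annotation must define ho_site and ho_inc_site")
    polymorphisms.sort(key=lambda p: p.recipient_pos)
    return GenomeMap(
        chromosomes=chromosomes,
        ho_site=ho_site,
        ho_inc_site=ho_inc_site,
        recipient_name=recipient_name,
        donor_name=donor_name,
        polymorphisms=polymorphisms,
        restriction_sites={"EcoRI": _scan_restriction(chromosomes)},
        control_region=control_region,
        donor_region=donor_region,
        homology_arms=arms,
        block_elements=blocks,
        config=None,
    )


def genomes_equal(a: GenomeMap, b: GenomeMap) -> bool:
    return (
        a.chromosomes == b.chromosomes
        and a.ho_site == b.ho_site
        and a.ho_inc_site == b.ho_inc_site
        and a.polymorphisms == b.polymorphisms
        and a.restriction_sites == b.restriction_sites
        and a.control_region == b.control_region
        and a.donor_region == b.donor_region
        and a.block_elements == b.block_elements
    )
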