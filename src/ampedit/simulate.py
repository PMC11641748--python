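"""Synthetic amplicon-seq and GUIDE-seq data with per-read ground truth.

The generator emulates the read structure the analysis assumes: a single
merged read spanning the whole amplicon, an NHEJ indel planted at the cut
site in an ``edit_fraction`` of target-template reads, and the three
sources of false editing that genetic variation produces -- population SNPs
near (but not at) the cut site, one high-frequency divergent homologous
allele differing by substitutions only, and co-amplified paralogous
templates that may differ by indels.  Uniform substitution-only sequencing
error is layered on top.  Every simulated read is paired with a
TruthRecord so recovery can be scored exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quant import Amplicon, GuideSpec, cut_site, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IndelSpectrum:
    """Distribution of NHEJ repair outcomes at the cut site.

    Deletions dominate NHEJ outcomes; lengths are short and roughly
    geometric.  Defaults: 80% deletions with geometric(p=0.5) lengths
    capped at 10 nt, insertions uniform on 1-3 nt.
    """

    deletion_prob: float = 0.8
    deletion_geom_p: float = 0.5
    max_deletion: int = 10
    max_insertion: int = 3

    def draw(self, rng: np.random.Generator) -> tuple[str, int]:
        if rng.random() < self.deletion_prob:
            length = min(int(rng.geometric(self.deletion_geom_p)), self.max_deletion)
            return "deletion", length
        return "insertion", int(rng.integers(1, self.max_insertion + 1))


@dataclass(frozen=True)
class SnpSpec:
    """A population SNP at a fixed offset from the cut site."""

    offset: int  # read position = cut_site + offset
    alt: str
    carrier_freq: float


@dataclass(frozen=True)
class HomologSpec:
    """One divergent homologous allele (substitution-only divergence)."""

    sequence: str
    frequency: float


@dataclass(frozen=True)
class ParalogSpec:
    """A co-amplified paralogous template and its mixture weight."""

    sequence: str
    weight: float


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulated sample.

    ``edit_fraction`` is the true probability that a primary-template read
    carries a Cas9 repair indel at the cut site.  Divergent-homolog and
    paralog reads are never edited: homolog divergence near the target is
    assumed to disrupt guide binding, and paralogs originate elsewhere in
    the genome.
    """

    edit_fraction: float = 0.0
    indel_spectrum: IndelSpectrum = field(default_factory=IndelSpectrum)
    snp_spec: tuple[SnpSpec, ...] = ()
    homolog_spec: Optional[HomologSpec] = None
    paralog_spec: tuple[ParalogSpec, ...] = ()
    error_rate: float = 0.0
    n_reads: int = 1000
    seed: int = 0

    def validate(self, amplicon: Amplicon, guide: GuideSpec) -> None:
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise ValueError("edit_fraction must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        weight_sum = sum(p.weight for p in self.paralog_spec)
        if self.homolog_spec is not None:
            if not 0.0 <= self.homolog_spec.frequency <= 1.0:
                raise ValueError("homolog frequency must lie in [0, 1]")
            weight_sum += self.homolog_spec.frequency
        if weight_sum > 1.0 + 1e-9:
            raise ValueError("homolog/paralog weights exceed 1; no mass left for the primary template")
        site = cut_site(guide, amplicon)
        for snp in self.snp_spec:
            if not 0.0 <= snp.carrier_freq <= 1.0:
                raise ValueError("SNP carrier frequency must lie in [0, 1]")
            if snp.offset in (-1, 0):
                raise ValueError(
                    "SNP offsets -1 and 0 fall inside the 2-nt quantification window; "
                    "the SNP scenario models variation outside it"
                )
            pos = site + snp.offset
            if not 0 <= pos < len(amplicon):
                raise ValueError(f"SNP offset {snp.offset} falls outside the amplicon")
        for par in self.paralog_spec:
            if par.sequence == amplicon.sequence:
                warnings.warn("paralog template identical to the primary amplicon", stacklevel=2)
        if self.homolog_spec is not None and len(self.homolog_spec.sequence) != len(amplicon):
            raise ValueError("homolog must differ from the amplicon by substitutions only (equal length)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    origin: str  # primary | homolog | paralog_<i>
    edited: bool
    events: tuple[str, ...]


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def make_amplicon(length: int, gc_fraction: float = 0.5, seed: int = 0) -> tuple[Amplicon, GuideSpec]:
    """Generate a random amplicon with exactly one planted protospacer+NGG.

    The protospacer is planted with >= 25 nt flanks on both sides of its
    23-nt footprint; generation retries until the protospacer is unique on
    both strands, so the guide's amplicon coordinates are unambiguous.
    """
    if length < 80:
        raise ValueError("amplicon length must be at least 80 nt")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    flank = 25
    for _ in range(100):
        seq = _random_seq(rng, length, gc_fraction)
        lo, hi = flank, length - flank - 23
        if hi < lo:
            raise ValueError("amplicon too short for 25-nt flanks around the protospacer")
        start = int(rng.integers(lo, hi + 1))
        protospacer = _random_seq(rng, 20, gc_fraction)
        pam = _random_seq(rng, 1, gc_fraction) + "GG"
        seq = seq[:start] + protospacer + pam + seq[start + 23 :]
        occurrences = seq.count(protospacer) + revcomp(seq).count(protospacer)
        if occurrences != 1:
            continue
        amplicon = Amplicon(id=f"amp_{seed}", sequence=seq)
        guide = GuideSpec(protospacer=protospacer, pam=pam, strand="+", protospacer_start=start)
        guide.validate_against(amplicon)
        return amplicon, guide
    raise RuntimeError("could not place a unique protospacer; try another seed")


def _apply_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[int(rng.integers(3))]
    return "".join(chars)


def _edit_template(seq: str, cut: int, spectrum: IndelSpectrum, rng: np.random.Generator) -> tuple[str, str]:
    """Apply one NHEJ indel whose reference interval covers the cut site."""
    kind, length = spectrum.draw(rng)
    if kind == "deletion":
        start = max(0, cut - math.ceil(length / 2))
        end = min(len(seq), start + length)
        return seq[:start] + seq[end:], f"del:{start}-{end}"
    ins = _random_seq(rng, length)
    return seq[:cut] + ins + seq[cut:], f"ins:{cut}:{ins}"


def simulate_reads(
    amplicon: Amplicon,
    guide: GuideSpec,
    scenario: ScenarioSpec,
    read_prefix: str = "read",
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Simulate one sample of full-amplicon merged reads plus ground truth.

    Per read: draw the template of origin (primary / homolog / paralog_i)
    from the mixture weights, apply SNPs to primary reads by carrier
    frequency, apply one cut-covering NHEJ indel to primary reads with
    probability ``edit_fraction``, then uniform substitution error.
    """
    scenario.validate(amplicon, guide)
    rng = np.random.default_rng(scenario.seed)
    site = cut_site(guide, amplicon)

    origins = ["primary"]
    templates = [amplicon.sequence]
    weights = [1.0]
    if scenario.homolog_spec is not None:
        origins.append("homolog")
        templates.append(scenario.homolog_spec.sequence)
        weights.append(scenario.homolog_spec.frequency)
        weights[0] -= scenario.homolog_spec.frequency
    for i, par in enumerate(scenario.paralog_spec):
        origins.append(f"paralog_{i}")
        templates.append(par.sequence)
        weights.append(par.weight)
        weights[0] -= par.weight
    weights = np.clip(np.array(weights), 0.0, None)
    weights /= weights.sum()

    reads: list[SimRead] = []
    truths: list[TruthRecord] = []
    origin_draw = rng.choice(len(origins), size=scenario.n_reads, p=weights)
    for i in range(scenario.n_reads):
        oi = int(origin_draw[i])
        origin = origins[oi]
        seq = templates[oi]
        events: list[str] = []
        if origin == "primary":
            for snp in scenario.snp_spec:
                if rng.random() < snp.carrier_freq:
                    pos = site + snp.offset
                    if seq[pos] != snp.alt:
                        seq = seq[:pos] + snp.alt + seq[pos + 1 :]
                        events.append(f"snp:{pos}:{snp.alt}")
        edited = False
        if origin == "primary" and rng.random() < scenario.edit_fraction:
            edited = True
            seq, ev = _edit_template(seq, site, scenario.indel_spectrum, rng)
            events.append(ev)
        seq = _apply_error(seq, scenario.error_rate, rng)
        rid = f"{read_prefix}{i:06d}"
        reads.append(SimRead(rid, seq))
        truths.append(TruthRecord(rid, origin, edited, tuple(events)))
    return reads, truths


def simulate_paired_samples(
    amplicon: Amplicon,
    guide: GuideSpec,
    base_scenario: ScenarioSpec,
    treated_edit_fraction: float,
) -> tuple[list[SimRead], list[SimRead], pd.DataFrame]:
    """Simulate an sgRNA-free control and a treated sample.

    Both samples share the identical variation structure (SNPs, homolog,
    paralogs, error rate); only the treated sample contains edited reads.
    Child seeds are derived deterministically from the scenario seed.
    """
    s1, s2 = np.random.SeedSequence(base_scenario.seed).generate_state(2) % (2**31)
    control_scn = replace(base_scenario, edit_fraction=0.0, seed=int(s1))
    treated_scn = replace(base_scenario, edit_fraction=treated_edit_fraction, seed=int(s2))
    control, truth_c = simulate_reads(amplicon, guide, control_scn, read_prefix="ctrl")
    treated, truth_t = simulate_reads(amplicon, guide, treated_scn, read_prefix="trt")
    truth = pd.DataFrame(
        [
            {"read_id": t.read_id, "sample": s, "origin": t.origin, "edited": t.edited, "events": ";".join(t.events)}
            for s, recs in (("control", truth_c), ("treated", truth_t))
            for t in recs
        ]
    )
    return control, treated, truth


def divergent_homolog(
    amplicon: Amplicon, guide: GuideSpec, offsets: Sequence[int], seed: int = 0
) -> HomologSpec:
    """Build a homologous allele substituted at the given cut-site offsets."""
    rng = np.random.default_rng(seed)
    site = cut_site(guide, amplicon)
    chars = list(amplicon.sequence)
    for off in offsets:
        pos = site + off
        if not 0 <= pos < len(chars):
            raise ValueError(f"offset {off} outside the amplicon")
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[int(rng.integers(3))]
    return HomologSpec(sequence="".join(chars), frequency=0.0)


# ---------------------------------------------------------------------------
# GUIDE-seq style simulation

#: Canonical GUIDE-seq double-stranded oligodeoxynucleotide tag (34 nt).
DEFAULT_DSODN = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"


@dataclass(frozen=True)
class PlantedSite:
    """A genomic protospacer+PAM footprint to tag with dsODN reads.

    ``position`` is the 0-based forward-strand start of the 23-nt
    footprint; mismatches (relative to the guide) are confined to the
    protospacer, the PAM stays NGG.
    """

    position: int
    strand: str
    mismatches: int
    read_count: int


def _plant_footprint(
    genome: list[str], site: PlantedSite, protospacer: str, rng: np.random.Generator
) -> tuple[int, list[int]]:
    """Write the (possibly mismatched) target into the genome; return cut and mismatch offsets."""
    proto = list(protospacer)
    mm_positions = sorted(rng.choice(20, size=site.mismatches, replace=False).tolist()) if site.mismatches else []
    for p in mm_positions:
        choices = [b for b in "ACGT" if b != proto[p]]
        proto[p] = choices[int(rng.integers(3))]
    proto_seq = "".join(proto)
    pam = "TGG"
    if site.strand == "+":
        footprint = proto_seq + pam
        cut = site.position + 17
    else:
        footprint = revcomp(proto_seq + pam)
        cut = site.position + 3 + (20 - 17)
    genome[site.position : site.position + 23] = list(footprint)
    return cut, mm_positions


def simulate_guideseq(
    genome_length: int,
    planted_sites: Sequence[PlantedSite],
    protospacer: str,
    dsodn_sequence: str = DEFAULT_DSODN,
    read_length: int = 150,
    n_background_reads: int = 200,
    seed: int = 0,
    contig: str = "chr_sim",
) -> tuple[dict[str, str], list[SimRead], pd.DataFrame]:
    """Simulate a small genome with dsODN-tagged reads at planted cut sites.

    Each planted site emits ``read_count`` reads consisting of genomic
    sequence with the dsODN inserted bluntly at the cut position; half the
    reads are reverse-complemented.  Background reads carry no tag.
    Returns (genome dict, reads, truth table with one row per site).
    """
    rng = np.random.default_rng(seed)
    margin = read_length + 10
    if genome_length < 2 * margin + 100:
        raise ValueError("genome too short for the requested read length")
    occupied: list[tuple[int, int]] = []
    for site in planted_sites:
        if site.strand not in "+-":
            raise ValueError("site strand must be '+' or '-'")
        if not margin <= site.position <= genome_length - margin - 23:
            raise ValueError(f"planted site at {site.position} too close to the genome edge")
        for a, b in occupied:
            if site.position < b and site.position + 23 > a:
                raise ValueError("planted sites overlap")
        occupied.append((site.position, site.position + 23))

    genome_chars = list(_random_seq(rng, genome_length))
    truth_rows = []
    site_cuts = []
    for site in planted_sites:
        cut, mm_pos = _plant_footprint(genome_chars, site, protospacer, rng)
        site_cuts.append((site, cut, mm_pos))
    genome = "".join(genome_chars)

    reads: list[SimRead] = []
    idx = 0
    for site, cut, mm_pos in site_cuts:
        for _ in range(site.read_count):
            up = int(rng.integers(25, min(61, read_length - len(dsodn_sequence))))
            down = read_length - up - len(dsodn_sequence)
            seq = genome[cut - up : cut] + dsodn_sequence + genome[cut : cut + max(down, 0)]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SimRead(f"gs{idx:06d}", seq))
            idx += 1
        truth_rows.append(
            {
                "contig": contig,
                "cut_position": cut,
                "footprint_start": site.position,
                "strand": site.strand,
                "mismatches": site.mismatches,
                "mismatch_offsets": ";".join(map(str, mm_pos)),
                "read_count": site.read_count,
            }
        )
    for _ in range(n_background_reads):
        start = int(rng.integers(0, genome_length - read_length))
        seq = genome[start : start + read_length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SimRead(f"gs{idx:06d}", seq))
        idx += 1
    truth = pd.DataFrame(truth_rows, columns=[
        "contig", "cut_position", "footprint_start", "strand", "mismatches", "mismatch_offsets", "read_count",
    ])
    return {contig: genome}, reads, truth


# ---------------------------------------------------------------------------
# Expression-vs-editing tables


def simulate_expression_editing_table(
    n_genes: int,
    correlation_target: float,
    seed: int = 0,
    n_replicates: int = 6,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate gene counts and per-gene editing with a target rank correlation.

    A Gaussian copula couples the latent expression level and the editing
    efficiency so that their population Spearman correlation equals
    ``correlation_target`` (via rho_pearson = 2 sin(pi rho_s / 6)).  Counts
    are negative-binomial across replicates (the study design has six
    embryo replicates); efficiencies are mapped through a right-skewed
    beta quantile, so they are deliberately non-normal.
    """
    if n_genes < 5:
        raise ValueError("n_genes must be at least 5")
    if abs(correlation_target) > 1:
        raise ValueError("correlation_target must lie in [-1, 1]")
    from scipy import stats

    rng = np.random.default_rng(seed)
    rho_p = 2 * math.sin(math.pi * correlation_target / 6)
    z1 = rng.standard_normal(n_genes)
    z2 = rho_p * z1 + math.sqrt(1 - rho_p**2) * rng.standard_normal(n_genes)
    mean_expr = np.exp(5.0 + 1.5 * z1)
    r = 1.0 / dispersion
    p = r / (r + mean_expr)
    counts = rng.negative_binomial(r, p[:, None], size=(n_genes, n_replicates))
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(counts, index=genes, columns=[f"rep{j + 1}" for j in range(n_replicates)])
    editing = pd.Series(stats.beta.ppf(stats.norm.cdf(z2), a=1.2, b=3.0), index=genes, name="aee2")
    return counts_df, editing
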