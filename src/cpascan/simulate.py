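"""Synthetic pre-mRNA generator with planted CPA elements.

Emulates the statistical structure the analysis assumes: each gene carries
one constitutive CPA site whose surroundings contain (subject to
per-element inclusion probabilities) the five core elements — UGUA in the
-100..-30 upstream stretch, a PAS hexamer starting near -30, a U-rich run
within +/-15 nt of the site, the CA/UA cleavage dinucleotide at the site,
and a GU-rich 8-mer between +20 and +40 downstream — planted into a
configurable (A/U-rich by default, matching the composition of the human
genome) background.  Cryptic decoys carrying only a subset of the elements
are planted elsewhere in the gene; optional weak alternative annotated
sites and optional U1-site planting near decoys exercise the site-selection
and second-stage logic.  PSE/RPM metadata are sampled so that the intended
constitutive site attains the maximal PSE x RPM in its gene unless
significance scrambling is requested.

Element "strength" interpolates between consensus planting (1.0) and pure
background (0.0) as a per-position corruption probability.  Genes are laid
out on chromosomes chr1..chr22 + chrX round-robin, on alternating strands,
separated by background spacers, and emitted in exactly the dialects the
I/O layer reads (FASTA, BED6, sites TSV, JSON manifest).  Scale defaults
(400 genes, median 5 kb) keep the full pipeline desk-sized while leaving
every gene enough tiling windows to sustain the 30:1 negative subsampling;
real pre-mRNAs have a median closer to 23 kb.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from cpascan.features import BinGrid, FeatureMatrix
from cpascan.motifs import PAS_HEXAMER_WEIGHTS, RNA_BASES
from cpascan.sequence_io import (
    CPASite,
    GeneModel,
    GenomicInterval,
    reverse_complement,
    write_fasta,
    write_sites_table,
)

ELEMENT_NAMES = ("ugua", "pas", "urich", "ca", "dse")

ELEMENT_LENGTHS = {"ugua": 4, "pas": 6, "urich": 6, "ca": 2, "dse": 8}

DECOY_POLICIES = {
    "pas_only": ("pas",),
    "pas_dse": ("pas", "ca", "dse"),
    "no_ugua": ("pas", "urich", "ca", "dse"),
    "no_pas": ("ugua", "urich", "ca", "dse"),
}

#: Default mapping from planted elements to the baseline-registry
#: representation expected to detect them.
ELEMENT_REPRESENTATION = {
    "ugua": "ugua",
    "pas": "pas_hexamer",
    "urich": "u_rich",
    "ca": "cleavage_ca_ua",
    "dse": "dse_gu8",
}

_SPLICE_DONOR_CONSENSUS = "CAGGUAAGU"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ElementParams:
    """Inclusion probability and planting fidelity of one element."""

    inclusion: float = 1.0
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclusion <= 1.0:
            raise SimulationError("inclusion probability must be in [0, 1]")
        if not 0.0 <= self.strength <= 1.0:
            raise SimulationError("strength must be in [0, 1]")


def default_element_params() -> dict[str, ElementParams]:
    """Per-element defaults: a near-ubiquitous, high-fidelity PAS and
    cleavage dinucleotide; strong but not universal DSE; and weak,
    degraded UGUA and U-rich elements.

    The asymmetry is deliberate: it emulates the importance structure of
    real constitutive CPA sites, where the PAS and DSE carry most of the
    discriminative signal while UGUA (a short word common in background
    sequence, loosely positioned over -100..-30) and the degenerate U-rich
    element contribute comparatively little.
    """
    return {
        "ugua": ElementParams(inclusion=0.60, strength=0.85),
        "pas": ElementParams(inclusion=1.0, strength=0.97),
        "urich": ElementParams(inclusion=0.80, strength=0.75),
        "ca": ElementParams(inclusion=1.0, strength=1.0),
        "dse": ElementParams(inclusion=0.95, strength=0.92),
    }


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic benchmark."""

    n_genes: int = 400
    gene_length_median: float = 5000.0
    gene_length_sigma: float = 0.30
    min_gene_length: int = 1600
    background: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    element_params: dict[str, ElementParams] = field(
        default_factory=default_element_params
    )
    decoy_rate_per_kb: float = 0.30
    decoy_policy: str = "pas_only"
    #: plant the canonical AAUAAA at every site (default); when True, the
    #: hexamer is sampled per site from the usage-weighted variant table,
    #: which makes a sizeable minority of sites carry weakly scoring PAS
    #: words (more realistic, harder recovery)
    pas_variant_sampling: bool = False
    alt_site_prob: float = 0.5
    plant_u1_near_decoys: bool = False
    scramble_significance: bool = False
    spacer: int = 300
    n_chromosomes: int = 23  # chr1..chr22 + chrX
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg < 0).any():
            raise SimulationError("background must be 4 probabilities summing to 1")
        if self.decoy_policy not in DECOY_POLICIES:
            raise SimulationError(
                f"unknown decoy policy {self.decoy_policy!r}; "
                f"choose from {sorted(DECOY_POLICIES)}"
            )
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if self.min_gene_length < 1200:
            raise SimulationError("min_gene_length must be >= 1200")
        for name in ELEMENT_NAMES:
            if name not in self.element_params:
                raise SimulationError(f"missing element_params entry {name!r}")

    def chrom_names(self) -> list[str]:
        names = [f"chr{i}" for i in range(1, min(self.n_chromosomes, 23))]
        if self.n_chromosomes >= 23:
            names.append("chrX")
        return names


@dataclass(frozen=True)
class DecoySite:
    """A planted cryptic decoy: partial element set, never annotated."""

    gene_id: str
    position: GenomicInterval  # single base, cleavage-base convention
    tx_offset: int  # transcript coordinate of the decoy base
    elements: tuple[str, ...]


@dataclass
class TruthSet:
    """Everything the generator knows about what it planted."""

    spec: GeneratorSpec
    genes: list[GeneModel]
    sequences: dict[str, str]  # chrom -> genomic sequence
    constitutive_sites: dict[str, CPASite]
    alt_sites: list[CPASite]
    decoys: list[DecoySite]
    site_tx_offsets: dict[str, int]  # gene -> transcript offset of the site
    element_offsets: dict[str, dict[str, int]]  # gene -> element -> offset rel. site
    resampled_genes: int = 0

    @property
    def all_known_sites(self) -> list[CPASite]:
        return list(self.constitutive_sites.values()) + list(self.alt_sites)

    def gene_models(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def transcript(self, gene_id: str) -> str:
        gm = self.gene_models()[gene_id]
        seq = self.sequences[gm.span.chrom][gm.span.start : gm.span.end]
        return reverse_complement(seq) if gm.span.strand == "-" else seq

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome_fasta": outdir / "genome.fa",
            "genes_bed": outdir / "genes.bed",
            "utr_bed": outdir / "three_prime_utrs.bed",
            "sites_tsv": outdir / "cpa_sites.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.sequences, paths["genome_fasta"])
        with open(paths["genes_bed"], "w", newline="\n") as fh:
            for g in self.genes:
                s = g.span
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{g.gene_id}\t0\t{s.strand}\n")
        with open(paths["utr_bed"], "w", newline="\n") as fh:
            for g in self.genes:
                u = g.three_prime_utr
                if u is not None:
                    fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{g.gene_id}\t0\t{u.strand}\n")
        write_sites_table(self.all_known_sites, paths["sites_tsv"])
        manifest = {
            "spec": _spec_to_jsonable(self.spec),
            "n_genes": len(self.genes),
            "n_alt_sites": len(self.alt_sites),
            "n_decoys": len(self.decoys),
            "resampled_genes": self.resampled_genes,
            "decoys": [
                {
                    "gene_id": d.gene_id,
                    "chrom": d.position.chrom,
                    "position": d.position.start,
                    "strand": d.position.strand,
                    "elements": list(d.elements),
                }
                for d in self.decoys
            ],
            "site_tx_offsets": self.site_tx_offsets,
            "element_offsets": self.element_offsets,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
        return paths


def _spec_to_jsonable(spec: GeneratorSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["element_params"] = {
        k: dataclasses.asdict(v) for k, v in spec.element_params.items()
    }
    return d


def random_background(length: int, composition: Sequence[float], rng) -> np.ndarray:
    """Encoded random sequence with the given A/C/G/U composition."""
    return rng.choice(4, size=length, p=np.asarray(composition, dtype=float))


def _corrupt(codes: np.ndarray, strength: float, composition, rng) -> np.ndarray:
    """Replace each position with a background draw with prob 1 - strength."""
    out = codes.copy()
    mask = rng.random(len(codes)) >= strength
    if mask.any():
        out[mask] = rng.choice(4, size=int(mask.sum()), p=np.asarray(composition))
    return out


def _encode(s: str) -> np.ndarray:
    return np.array([RNA_BASES.index(b) for b in s], dtype=np.int64)


def _decode(codes: np.ndarray) -> str:
    return "".join(RNA_BASES[c] for c in codes)


def _sample_pas_variant(rng) -> str:
    variants = list(PAS_HEXAMER_WEIGHTS)
    weights = np.array([PAS_HEXAMER_WEIGHTS[v] for v in variants], dtype=float)
    return variants[int(rng.choice(len(variants), p=weights / weights.sum()))]


def _element_word(name: str, rng, pas_variant_sampling: bool = False) -> str:
    if name == "ugua":
        return "UGUA"
    if name == "pas":
        return _sample_pas_variant(rng) if pas_variant_sampling else "AAUAAA"
    if name == "urich":
        return "UUUUUU"
    if name == "ca":
        return ("CA", "UA")[int(rng.integers(2))]
    if name == "dse":
        return _decode(rng.choice([2, 3], size=8))  # random G/U run
    raise SimulationError(f"unknown element {name!r}")


def _element_offset(name: str, rng) -> int:
    """Start offset of the planted word relative to the cleavage base."""
    if name == "ugua":
        return int(rng.integers(-100, -30 + 1))
    if name == "pas":
        return -30 + int(rng.integers(-2, 3))
    if name == "urich":
        return int(rng.integers(-15, 10))  # 6-mer stays within +/-15
    if name == "ca":
        return -1  # C/U at -1, A at the cleavage base
    if name == "dse":
        return int(rng.integers(20, 33))  # 8-mer ends by +40
    raise SimulationError(f"unknown element {name!r}")


def _plant_elements(
    tx: np.ndarray,
    site: int,
    params: Mapping[str, ElementParams],
    composition,
    rng,
    only: Sequence[str] | None = None,
    force_include: bool = False,
    pas_variant_sampling: bool = False,
) -> dict[str, int]:
    """Plant elements around a site in a transcript; returns the offsets
    (relative to the site) of the elements actually planted."""
    planted: dict[str, int] = {}
    for name in ELEMENT_NAMES:
        if only is not None and name not in only:
            continue
        p = params[name]
        if not force_include and rng.random() >= p.inclusion:
            continue
        word = _encode(_element_word(name, rng, pas_variant_sampling))
        word = _corrupt(word, p.strength, composition, rng)
        rel = _element_offset(name, rng)
        start = site + rel
        tx[start : start + len(word)] = word
        planted[name] = rel
    return planted


def generate(spec: GeneratorSpec) -> TruthSet:
    """Generate a synthetic genome, gene models, and CPA-site annotations.

    Deterministic per seed.  Genes whose sampled geometry cannot host the
    required placements are resampled (counted in ``resampled_genes``).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = spec.chrom_names()
    per_chrom_parts: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    per_chrom_pos: dict[str, int] = {c: 0 for c in chroms}

    genes: list[GeneModel] = []
    constitutive: dict[str, CPASite] = {}
    alt_sites: list[CPASite] = []
    decoys: list[DecoySite] = []
    site_tx: dict[str, int] = {}
    element_offsets: dict[str, dict[str, int]] = {}
    resampled = 0

    mu = np.log(spec.gene_length_median)
    for g in range(spec.n_genes):
        gene_id = f"G{g:04d}"
        chrom = chroms[g % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"

        for _attempt in range(20):
            length = int(np.exp(rng.normal(mu, spec.gene_length_sigma)))
            if length >= spec.min_gene_length:
                break
            resampled += 1
        else:
            raise SimulationError("could not sample a feasible gene length")
        # cleavage base in transcript coordinates; leaves a full downstream
        # flank inside the gene and upstream room for elements and decoys
        t_site = length - int(rng.integers(260, 451))

        tx = random_background(length, spec.background, rng)
        planted = _plant_elements(
            tx, t_site, spec.element_params, spec.background, rng,
            pas_variant_sampling=spec.pas_variant_sampling,
        )

        # cryptic decoys: partial element sets upstream of the site
        decoy_elements = DECOY_POLICIES[spec.decoy_policy]
        n_decoys = int(rng.poisson(spec.decoy_rate_per_kb * length / 1000.0))
        decoy_tx: list[tuple[int, tuple[str, ...]]] = []
        lo, hi = 600, t_site - 600
        if hi > lo:
            candidates = rng.integers(lo, hi, size=n_decoys)
            for cand in sorted(int(c) for c in candidates):
                if decoy_tx and cand - decoy_tx[-1][0] < 350:
                    continue
                _plant_elements(
                    tx, cand, spec.element_params, spec.background, rng,
                    only=decoy_elements, force_include=True,
                    pas_variant_sampling=spec.pas_variant_sampling,
                )
                if spec.plant_u1_near_decoys:
                    # fixed offset so the positional profile across decoy
                    # windows shows the enrichment (a roaming offset would
                    # wash out of per-position medians)
                    u1_rel = -40
                    word = _encode(_SPLICE_DONOR_CONSENSUS)
                    word = _corrupt(word, 0.95, spec.background, rng)
                    tx[cand + u1_rel : cand + u1_rel + len(word)] = word
                decoy_tx.append((cand, decoy_elements))

        # genomic placement
        start = per_chrom_pos[chrom] + spec.spacer
        genomic = tx if strand == "+" else _encode(
            reverse_complement(_decode(tx))
        )
        per_chrom_parts[chrom].append(
            random_background(spec.spacer, spec.background, rng)
        )
        per_chrom_parts[chrom].append(genomic)
        per_chrom_pos[chrom] = start + length

        span = GenomicInterval(chrom, start, start + length, strand)

        def to_genomic(tx_offset: int) -> int:
            if strand == "+":
                return start + tx_offset
            return start + length - 1 - tx_offset

        # 3'UTR: upstream stretch ending just past the site
        utr_up = int(rng.integers(300, 801))
        utr_lo_tx = max(0, t_site - utr_up)
        utr_hi_tx = min(length, t_site + 100)
        g_a, g_b = to_genomic(utr_lo_tx), to_genomic(utr_hi_tx - 1)
        utr = GenomicInterval(chrom, min(g_a, g_b), max(g_a, g_b) + 1, strand)
        gene = GeneModel(gene_id, span, utr)
        genes.append(gene)

        site_pos = to_genomic(t_site)
        pse = float(rng.uniform(70, 100))
        rpm = float(np.exp(rng.normal(np.log(2.0), 0.6)))
        const_site = CPASite(
            gene_id, GenomicInterval(chrom, site_pos, site_pos + 1, strand), pse, rpm
        )
        constitutive[gene_id] = const_site
        site_tx[gene_id] = t_site
        element_offsets[gene_id] = planted

        if rng.random() < spec.alt_site_prob:
            alt_tx = t_site - int(rng.integers(100, min(251, max(101, utr_up))))
            _plant_elements(
                tx, alt_tx, spec.element_params, spec.background, rng,
                only=("pas",), force_include=True,
                pas_variant_sampling=spec.pas_variant_sampling,
            )
            # replant into the genomic copy (tx was already copied for '+')
            word_region = tx[alt_tx - 40 : alt_tx + 45]
            if strand == "+":
                genomic[alt_tx - 40 : alt_tx + 45] = word_region
            else:
                genomic[length - (alt_tx + 45) : length - (alt_tx - 40)] = _encode(
                    reverse_complement(_decode(word_region))
                )
            alt_pse = float(rng.uniform(5, 50))
            alt_rpm = float(np.exp(rng.normal(np.log(0.5), 0.6)))
            if not spec.scramble_significance:
                # intended constitutive site keeps the max PSE x RPM
                cap = const_site.significance * 0.8
                if alt_pse * alt_rpm >= cap:
                    alt_rpm = cap / alt_pse * rng.uniform(0.5, 0.99)
            else:
                alt_pse, alt_rpm = pse, rpm * 2.0  # deliberately outrank
            alt_pos = to_genomic(alt_tx)
            alt_sites.append(
                CPASite(
                    gene_id,
                    GenomicInterval(chrom, alt_pos, alt_pos + 1, strand),
                    min(alt_pse, 100.0),
                    alt_rpm,
                )
            )

        for cand, elems in decoy_tx:
            pos = to_genomic(cand)
            decoys.append(
                DecoySite(
                    gene_id,
                    GenomicInterval(chrom, pos, pos + 1, strand),
                    cand,
                    tuple(elems),
                )
            )

    sequences = {}
    for chrom in chroms:
        parts = per_chrom_parts[chrom]
        parts.append(random_background(spec.spacer, spec.background, rng))
        sequences[chrom] = _decode(np.concatenate(parts))

    return TruthSet(
        spec=spec,
        genes=genes,
        sequences=sequences,
        constitutive_sites=constitutive,
        alt_sites=alt_sites,
        decoys=decoys,
        site_tx_offsets=site_tx,
        element_offsets=element_offsets,
        resampled_genes=resampled,
    )


def element_recovery_census(
    truth: TruthSet,
    matrix: FeatureMatrix,
    grid: BinGrid,
    flank: int = 250,
    element_to_rep: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Fraction of positives whose max-scoring bin for each element's
    representation contains the planted offset.

    Short elements (UGUA, CA/UA, G/U runs) recur by chance, so several bins
    can attain the representation's maximum score; a window counts as a hit
    when *any* bin attaining the maximum contains the planted start offset
    (an exact planted match always attains the maximum, so at full strength
    the detection fraction is 1).  ``matrix`` must hold the positive windows
    in gene order with ``example_ids`` set to gene ids.
    """
    rep_map = dict(ELEMENT_REPRESENTATION if element_to_rep is None else element_to_rep)
    from cpascan.features import parse_feature_name

    cols_by_rep: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for col, name in enumerate(matrix.feature_names_):
        rep, _b, lo, hi = parse_feature_name(name)
        cols_by_rep[rep].append((col, lo, hi))

    hits: dict[str, int] = defaultdict(int)
    totals: dict[str, int] = defaultdict(int)
    for row, gene_id in enumerate(matrix.example_ids):
        offsets = truth.element_offsets.get(gene_id, {})
        for element, rel in offsets.items():
            rep = rep_map.get(element)
            if rep is None or rep not in cols_by_rep:
                continue
            cells = cols_by_rep[rep]
            values = matrix.values[row, [c for c, _, _ in cells]]
            top = values.max()
            planted_start = flank + rel
            totals[element] += 1
            if any(
                lo <= planted_start < hi
                for (_c, lo, hi), v in zip(cells, values)
                if v == top
            ):
                hits[element] += 1
    return {e: hits[e] / totals[e] for e in totals}


# ---------------------------------------------------------------------------
# Brute-force all-element co-occurrence in background sequence, using the
# same window geometry as the analytic specificity estimates.


def _windowed_any(occ: np.ndarray, n_positions: int) -> np.ndarray:
    """any(occ[p : p + n_positions]) for every p (cumulative-sum trick)."""
    csum = np.concatenate([[0], np.cumsum(occ.astype(np.int64))])
    limit = len(occ) - n_positions + 1
    if limit <= 0:
        return np.zeros(0, dtype=bool)
    return (csum[n_positions : n_positions + limit] - csum[:limit]) > 0


def _pattern_occurrences(enc: np.ndarray, word: str) -> np.ndarray:
    codes = _encode(word)
    k = len(codes)
    if len(enc) < k:
        return np.zeros(0, dtype=bool)
    occ = np.ones(len(enc) - k + 1, dtype=bool)
    for j, c in enumerate(codes):
        occ &= enc[j : j + len(enc) - k + 1] == c
    return occ


def count_joint_element_sites(seq_or_codes) -> tuple[int, int]:
    """Count bases around which all five core elements co-occur.

    For base ``i`` the search windows mirror the analytic geometry: UGUA
    starting in ``[i-100, i-1]`` (100 positions), a PAS variant in
    ``[i-30, i-11]`` (20), UUUU in ``[i-15, i+14]`` (30), CA or UA starting
    exactly at ``i-1`` (1), and a G/U 8-mer starting in ``[i+10, i+49]``
    (40).  Returns ``(n_joint_bases, n_evaluable_bases)``.
    """
    enc = (
        _encode(seq_or_codes)
        if isinstance(seq_or_codes, str)
        else np.asarray(seq_or_codes)
    )
    G = len(enc)
    lo_i, hi_i = 100, G - 57  # full windows on both sides
    if hi_i <= lo_i:
        return 0, 0
    idx = np.arange(lo_i, hi_i)

    ugua_any = _windowed_any(_pattern_occurrences(enc, "UGUA"), 100)
    pas_occ = np.zeros(G - 6 + 1, dtype=bool)
    for variant in PAS_HEXAMER_WEIGHTS:
        pas_occ |= _pattern_occurrences(enc, variant)
    pas_any = _windowed_any(pas_occ, 20)
    u4_any = _windowed_any(_pattern_occurrences(enc, "UUUU"), 30)
    ca_occ = _pattern_occurrences(enc, "CA") | _pattern_occurrences(enc, "UA")
    gu = (enc == 2) | (enc == 3)
    run8 = np.ones(G - 8 + 1, dtype=bool)
    for j in range(8):
        run8 &= gu[j : j + G - 8 + 1]
    dse_any = _windowed_any(run8, 40)

    joint = (
        ugua_any[idx - 100]
        & pas_any[idx - 30]
        & u4_any[idx - 15]
        & ca_occ[idx - 1]
        & dse_any[idx + 10]
    )
    return int(joint.sum()), int(len(idx))


def empirical_joint_rate(
    total_length: int,
    seed: int,
    composition: Sequence[float] = (0.30, 0.20, 0.20, 0.30),
    chunk: int = 1_000_000,
) -> float:
    """Per-base rate of all-five-element co-occurrence in random sequence.

    The default composition is the generator's A/U-rich background.  Under
    that composition two opposing effects roughly cancel relative to the
    uniform analytic product: occurrence clumping of the self-overlapping
    patterns (UUUU, G/U runs) lowers the per-window hit probability below
    the expected-count approximation, while the A/U bias raises the
    per-placement match probabilities above the uniform model's.
    """
    rng = np.random.default_rng(seed)
    joint, evaluable = 0, 0
    remaining = total_length
    while remaining > 0:
        n = min(chunk, remaining)
        codes = random_background(n, composition, rng)
        j, e = count_joint_element_sites(codes)
        joint += j
        evaluable += e
        remaining -= n
    if evaluable == 0:
        raise SimulationError("sequence too short to evaluate any base")
    return joint / evaluable
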