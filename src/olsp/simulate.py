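"""Synthetic metabarcoding runs with ground truth.

Emulates the study design end to end so the whole pipeline is testable
without any external data: three COI primer sets amplifying overlapping
windows of species-specific templates, samples amplified in triplicate
PCRs labelled by 12 forward x 8 reverse 11-13 nt tags, two mock
communities (7 prey at 0.2 plus the predator *Zingel asper* at 0.8
relative DNA concentration) and four kinds of negative controls per run,
PCR substitution errors, tag switching, low-level contamination of
negatives, and planted habitat-incompatible contaminants in eDNA
samples. Per-marker taxon dropout is realized structurally: a fraction
of taxa carry >= 3 mismatches in a marker's forward-primer binding site,
so that marker can never amplify them.

Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .design import (
    EDNA,
    MOCK,
    NEGATIVE_CATEGORIES,
    Marker,
    RunDesign,
    SampleRecord,
    write_design,
)
from .seqs import IUPAC, in_silico_pcr, realize_iupac, revcomp

# Primer sets used in vivo (Table-equivalent constants of this package).
PRIMERS: dict[str, Marker] = {
    "MFZR": Marker("MFZR", "TCCACTAATCACAARGATATTGGTAC", "WACTAATCAATTWCCAAATCCTCC"),
    "ZFZR": Marker("ZFZR", "AGATATTGGAACWTTATATTTTATTTTTGG", "WACTAATCAATTWCCAAATCCTCC"),
    "LFCR": Marker("LFCR", "RKTCAACMAATCATAAAGATATTGG", "CCBCCRATTAWAATKGGTATHAC"),
}

#: eDNA sample census: (predator, number of samples, habitat)
CENSUS: tuple[tuple[str, int, str], ...] = (
    ("Zingel asper", 46, "freshwater"),
    ("Pomatoschistus microps", 15, "brackish"),
    ("Pomatoschistus microps", 14, "brackish"),
    ("Unknown bat", 1, "terrestrial"),
    ("Myotis nattereri", 2, "terrestrial"),
    ("Pipistrellus pipistrellus", 1, "terrestrial"),
    ("Eptesicus serotinus", 1, "terrestrial"),
    ("Miniopterus schreibersii", 4, "terrestrial"),
    ("Barbastella barbastellus", 1, "terrestrial"),
    ("Rhinolophus euryale", 1, "terrestrial"),
    ("Rhinolophus ferrumequinum", 1, "terrestrial"),
    ("Myotis emarginatus", 1, "terrestrial"),
    ("Epiplatys infrafasciatus", 6, "freshwater"),
    ("Unknown spider", 3, "terrestrial"),
    ("Araneomorphae", 5, "terrestrial"),
    ("Pholcidae", 2, "terrestrial"),
    ("Micrathena schreibersi", 3, "terrestrial"),
)

#: mock community panel: (species, concentration, in Tpos1, in Tpos2, path)
MOCK_PANEL: tuple[tuple[str, float, bool, bool, tuple[str, ...]], ...] = (
    ("Ephemerella ignita", 0.2, True, True,
     ("Animalia", "Arthropoda", "Insecta", "Ephemeroptera", "Ephemerellidae", "Ephemerella")),
    ("Hydropsyche modesta", 0.2, True, True,
     ("Animalia", "Arthropoda", "Insecta", "Trichoptera", "Hydropsychidae", "Hydropsyche")),
    ("Oligoneuriella rhenana", 0.2, True, False,
     ("Animalia", "Arthropoda", "Insecta", "Ephemeroptera", "Oligoneuriidae", "Oligoneuriella")),
    ("Eisenia andrei", 0.2, True, False,
     ("Animalia", "Annelida", "Clitellata", "Haplotaxida", "Lumbricidae", "Eisenia")),
    ("Chironomus riparius", 0.2, True, True,
     ("Animalia", "Arthropoda", "Insecta", "Diptera", "Chironomidae", "Chironomus")),
    ("Dinocras cephalotes", 0.2, True, False,
     ("Animalia", "Arthropoda", "Insecta", "Plecoptera", "Perlidae", "Dinocras")),
    ("Phoxinus phoxinus", 0.2, True, False,
     ("Animalia", "Chordata", "Actinopterygii", "Cypriniformes", "Leuciscidae", "Phoxinus")),
    ("Hydropsyche instabilis", 0.2, False, True,
     ("Animalia", "Arthropoda", "Insecta", "Trichoptera", "Hydropsychidae", "Hydropsyche")),
    ("Gammarus pulex", 0.2, False, True,
     ("Animalia", "Arthropoda", "Malacostraca", "Amphipoda", "Gammaridae", "Gammarus")),
    ("Planorbarius corneus", 0.2, False, True,
     ("Animalia", "Mollusca", "Gastropoda", "Hygrophila", "Planorbidae", "Planorbarius")),
    ("Velia saulii", 0.2, False, True,
     ("Animalia", "Arthropoda", "Insecta", "Hemiptera", "Veliidae", "Velia")),
    ("Zingel asper", 0.8, True, True,
     ("Animalia", "Chordata", "Actinopterygii", "Perciformes", "Percidae", "Zingel")),
)

_MACRO_SCAFFOLDS = (
    ("Animalia", "Arthropoda", "Insecta", "Ephemeroptera", "Baetidae"),
    ("Animalia", "Arthropoda", "Insecta", "Diptera", "Chironomidae"),
    ("Animalia", "Arthropoda", "Insecta", "Diptera", "Cecidomyiidae"),
    ("Animalia", "Arthropoda", "Insecta", "Trichoptera", "Hydropsychidae"),
    ("Animalia", "Arthropoda", "Insecta", "Lepidoptera", "Noctuidae"),
    ("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Formicidae"),
    ("Animalia", "Arthropoda", "Insecta", "Coleoptera", "Carabidae"),
    ("Animalia", "Arthropoda", "Malacostraca", "Amphipoda", "Gammaridae"),
    ("Animalia", "Arthropoda", "Malacostraca", "Mysida", "Mysidae"),
    ("Animalia", "Arthropoda", "Collembola", "Entomobryomorpha", "Entomobryidae"),
    ("Animalia", "Mollusca", "Gastropoda", "Stylommatophora", "Helicidae"),
    ("Animalia", "Annelida", "Clitellata", "Haplotaxida", "Naididae"),
    ("Animalia", "Chordata", "Actinopterygii", "Cypriniformes", "Cyprinidae"),
)

_NON_MACRO_SCAFFOLDS = (
    ("Animalia", "Rotifera", "Monogononta", "Ploima", "Brachionidae"),
    ("Animalia", "Nematoda", "Chromadorea", "Rhabditida", "Rhabditidae"),
    ("Animalia", "Arthropoda", "Arachnida", "Acari", "Ixodidae"),
    ("Plantae", "Streptophyta", "Magnoliopsida", "Poales", "Poaceae"),
)

HABITATS = ("freshwater", "brackish", "terrestrial")

# Template geometry (all coordinates 0-based half-open on the template):
# [0,25) LFCR fwd site | [25,51) MFZR fwd site | [51,81) ZFZR fwd site |
# [81,241) species core | [241,264) LFCR rev site (rc) |
# [264,288) MFZR/ZFZR shared rev site (rc) | [288,318) tail.
WINDOWS = {  # marker -> (fwd site start, insert start, insert end, rev site end)
    "LFCR": (0, 25, 241, 264),
    "MFZR": (25, 51, 264, 288),
    "ZFZR": (51, 81, 264, 288),
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic data-generating process.

    Defaults reproduce the study conditions: the full eDNA census, three
    markers in triplicate (9 PCRs per sample), 12 forward / 8 reverse
    tags, Tpos1/Tpos2 mock compositions, and per-marker amplification
    success rates matching the observed in vivo MOTU coverage.
    """

    seed: int = 0
    n_taxa: int = 30  # random taxa beyond the mock panel
    frac_non_macro: float = 0.15
    marker_success: tuple[tuple[str, float], ...] = (
        ("MFZR", 0.50),
        ("ZFZR", 0.70),
        ("LFCR", 0.66),
    )
    primer_anneal_mismatches: int = 2  # annealing tolerance; dropouts plant 3
    reads_per_pcr: int = 1000
    sub_rate: float = 0.001  # per-base PCR/sequencing substitution rate
    tag_switch_rate: float = 0.01
    neg_contam_mean: float = 5.0  # Poisson mean reads per negative PCR
    contaminant_rate: float = 0.05  # per (eDNA sample, marker)
    contaminant_mean_reads: float = 10.0  # Poisson mean per replicate
    prey_mean: float = 3.0  # extra planted taxa per sample = 1 + Poisson
    abundance_sigma: float = 1.0  # log-normal abundance spread
    replicates: int = 3
    samples_per_run: int = 24  # eDNA samples per sequencing run
    n_edna_samples: int | None = None  # None = full census (107 samples)
    census: tuple[tuple[str, int, str], ...] = CENSUS


@dataclass
class RefTaxon:
    ref_id: str
    species: str
    path: tuple[str, ...]  # kingdom..species (7 names)
    template: str
    habitats: frozenset[str]
    is_macro: bool
    amplicons: dict[str, str | None]  # marker -> trimmed insert or None


@dataclass
class GroundTruth:
    #: (run, sample, marker, replicate) -> {species: planted read count}
    per_pcr_composition: dict[tuple[str, str, str, int], dict[str, int]] = field(default_factory=dict)
    #: eDNA sample -> {species: relative abundance}
    sample_taxa: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (sample, marker) -> contaminant species
    contaminants: dict[tuple[str, str], str] = field(default_factory=dict)
    #: per run: read_id -> (sample, marker, replicate, species, switched)
    provenance: dict[str, dict[str, tuple[str, str, int, str, bool]]] = field(default_factory=dict)
    #: sample -> sorted planted species (diet truth; no contaminants)
    planted: dict[str, list[str]] = field(default_factory=dict)
    #: sample -> planted species that received reads in >= 2 replicates of
    #: some marker, i.e. are detectable under the replicate-consensus rule
    expected_items: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticRun:
    config: SimConfig
    reference: list[RefTaxon]
    designs: dict[str, RunDesign]
    tags_fwd: list[str]
    tags_rev: list[str]
    reads: dict[str, list[tuple[str, str]]]  # run -> [(read_id, seq)]
    truth: GroundTruth

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(self.designs, outdir / "design.tsv")
        write_reference(self.reference, outdir / "reference.fasta", outdir / "taxonomy.tsv")
        write_habitat_table(self.reference, outdir / "habitat.tsv")
        write_mock_expectations(self.designs, outdir / "mocks.tsv")
        for run_id, reads in sorted(self.reads.items()):
            with open(outdir / f"reads_{run_id}.fastq", "w") as fh:
                for read_id, seq in reads:
                    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth = {
            "sample_taxa": self.truth.sample_taxa,
            "contaminants": {f"{s}|{m}": t for (s, m), t in self.truth.contaminants.items()},
            "planted": self.truth.planted,
            "expected_items": self.truth.expected_items,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# reference generation


def _mutate_site(site: str, pattern: str, rng, n_mut: int = 3) -> str:
    """Plant ``n_mut`` mismatches against the IUPAC ``pattern``."""
    site = list(site)
    positions = rng.choice(len(site), size=n_mut, replace=False)
    for pos in positions:
        allowed = IUPAC[pattern[pos]]
        options = sorted(set("ACGT") - allowed) or sorted(set("ACGT") - {site[pos]})
        site[pos] = options[rng.integers(len(options))]
    return "".join(site)


def _random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_reference(config: SimConfig, rng=None) -> list[RefTaxon]:
    """Species templates embedding all three primer-binding regions.

    Each template realizes every primer site from its IUPAC pattern; a
    taxon then loses marker m (structurally, for the whole study) with
    probability 1 - marker_success[m], implemented by planting three
    mismatches in m's forward-primer site. Mock-panel taxa are guaranteed
    at least one working marker, and the predator keeps all markers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    success = dict(config.marker_success)
    taxa: list[RefTaxon] = []

    def build(species, path6, habitats, is_macro, force_any=False, force_all=False):
        while True:
            lfcr_f = realize_iupac(PRIMERS["LFCR"].fwd, rng)
            mfzr_f = realize_iupac(PRIMERS["MFZR"].fwd, rng)
            zfzr_f = realize_iupac(PRIMERS["ZFZR"].fwd, rng)
            lfcr_r = realize_iupac(revcomp(PRIMERS["LFCR"].rev), rng)
            shared_r = realize_iupac(revcomp(PRIMERS["MFZR"].rev), rng)
            amplify = {m: bool(rng.random() < success[m]) for m in sorted(success)}
            if force_all:
                amplify = {m: True for m in amplify}
            if force_any and not any(amplify.values()):
                continue
            if not force_any or any(amplify.values()):
                break
        if not amplify["LFCR"]:
            lfcr_f = _mutate_site(lfcr_f, PRIMERS["LFCR"].fwd, rng)
        if not amplify["MFZR"]:
            mfzr_f = _mutate_site(mfzr_f, PRIMERS["MFZR"].fwd, rng)
        if not amplify["ZFZR"]:
            zfzr_f = _mutate_site(zfzr_f, PRIMERS["ZFZR"].fwd, rng)
        core = _random_seq(rng, 160)
        tail = _random_seq(rng, 30)
        template = lfcr_f + mfzr_f + zfzr_f + core + lfcr_r + shared_r + tail
        amplicons = {
            m: in_silico_pcr(template, PRIMERS[m].fwd, PRIMERS[m].rev, config.primer_anneal_mismatches)
            for m in PRIMERS
        }
        ref_id = f"ref_{len(taxa) + 1:04d}"
        taxa.append(
            RefTaxon(
                ref_id=ref_id,
                species=species,
                path=path6 + (species,),
                template=template,
                habitats=frozenset(habitats),
                is_macro=is_macro,
                amplicons=amplicons,
            )
        )

    for species, _conc, _t1, _t2, path6 in MOCK_PANEL:
        predator = species == "Zingel asper"
        build(species, path6, {"freshwater"}, True, force_any=True, force_all=predator)

    n_non_macro = int(round(config.n_taxa * config.frac_non_macro))
    for i in range(config.n_taxa):
        non_macro = i < n_non_macro
        pool = _NON_MACRO_SCAFFOLDS if non_macro else _MACRO_SCAFFOLDS
        scaffold = pool[int(rng.integers(len(pool)))]
        genus = f"{scaffold[4][:-2]}us{i + 1:03d}"
        species = f"{genus} sp{i + 1:03d}"
        n_hab = 1 + int(rng.random() < 0.5)
        habitats = set(rng.choice(HABITATS, size=n_hab, replace=False).tolist())
        build(species, scaffold + (genus,), habitats, not non_macro, force_any=True)
    return taxa


def write_reference(taxa: list[RefTaxon], fasta_path, taxonomy_path) -> None:
    with open(fasta_path, "w") as fh:
        for t in taxa:
            fh.write(f">{t.ref_id}\n{t.template}\n")
    ranks = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
    with open(taxonomy_path, "w") as fh:
        fh.write("ref_id\t" + "\t".join(ranks) + "\n")
        for t in taxa:
            fh.write(t.ref_id + "\t" + "\t".join(t.path) + "\n")


def write_habitat_table(taxa: list[RefTaxon], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\thabitats\n")
        for t in taxa:
            fh.write(f"{t.species}\t{','.join(sorted(t.habitats))}\n")


def write_mock_expectations(designs: dict[str, RunDesign], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttaxon\trole\n")
        for rd in designs.values():
            for sample_id, rec in sorted(rd.samples.items()):
                for taxon, role in rec.expected_taxa:
                    fh.write(f"{sample_id}\t{taxon}\t{role}\n")


# ---------------------------------------------------------------------------
# design generation


def generate_tags(rng, n: int, min_mm: int = 3) -> list[str]:
    """Rejection-sample ``n`` tags of length 11-13 with pairwise

    mismatches >= ``min_mm`` over the shared prefix."""
    tags: list[str] = []
    while len(tags) < n:
        length = int(rng.integers(11, 14))
        cand = _random_seq(rng, length)
        ok = True
        for t in tags:
            k = min(len(t), len(cand))
            if sum(1 for a, b in zip(t[:k], cand[:k]) if a != b) < min_mm:
                ok = False
                break
        if ok:
            tags.append(cand)
    return tags


def _slug(name: str) -> str:
    return "".join(c for c in name.replace(" ", "_") if c.isalnum() or c == "_")[:18]


def generate_design(
    config: SimConfig, rng=None
) -> tuple[dict[str, RunDesign], list[str], list[str]]:
    """The full PCR layout: runs, tag assignments, samples and controls.

    Samples are partitioned into sequencing runs of at most
    ``samples_per_run`` eDNA samples; every run carries its own Tpos1 and
    Tpos2 mocks and the four negative-control kinds, all amplified with
    each of the three markers in ``replicates`` PCRs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tags_fwd = generate_tags(rng, 12)
    tags_rev = generate_tags(rng, 8)

    edna: list[SampleRecord] = []
    idx = 0
    for predator, n, habitat in config.census:
        for _ in range(n):
            idx += 1
            edna.append(
                SampleRecord(
                    sample_id=f"edna_{idx:03d}_{_slug(predator)}",
                    category=EDNA,
                    predator=predator,
                    habitat=habitat,
                )
            )
    if config.n_edna_samples is not None:
        keep = sorted(
            rng.choice(len(edna), size=min(config.n_edna_samples, len(edna)), replace=False).tolist()
        )
        edna = [edna[i] for i in keep]

    mock_taxa = {
        "Tpos1": [(sp, "prey" if conc < 0.5 else "predator") for sp, conc, t1, _t2, _ in MOCK_PANEL if t1],
        "Tpos2": [(sp, "prey" if conc < 0.5 else "predator") for sp, conc, _t1, t2, _ in MOCK_PANEL if t2],
    }

    designs: dict[str, RunDesign] = {}
    chunks = [
        edna[i : i + config.samples_per_run] for i in range(0, len(edna), config.samples_per_run)
    ] or [[]]
    for run_no, chunk in enumerate(chunks, start=1):
        run_id = f"run{run_no:02d}"
        samples: dict[str, SampleRecord] = {}
        for rec in chunk:
            samples[rec.sample_id] = rec
        for mock_name, taxa in mock_taxa.items():
            sid = f"{mock_name}_{run_id}"
            samples[sid] = SampleRecord(sid, MOCK, expected_taxa=list(taxa))
        for kind in NEGATIVE_CATEGORIES:
            sid = f"{kind}_{run_id}"
            samples[sid] = SampleRecord(sid, kind)
        combos = [(f, r) for f in tags_fwd for r in tags_rev]
        n_pcrs = len(samples) * config.replicates
        if n_pcrs > len(combos):
            raise ValueError(
                f"{run_id}: {n_pcrs} PCRs per marker exceed {len(combos)} tag combinations; "
                f"reduce samples_per_run"
            )
        tag_map: dict[tuple[str, str, str], tuple[str, int]] = {}
        for marker in PRIMERS:
            for i, (sid, rep) in enumerate(
                (sid, rep) for sid in sorted(samples) for rep in range(1, config.replicates + 1)
            ):
                ftag, rtag = combos[i]
                tag_map[(marker, ftag, rtag)] = (sid, rep)
        rd = RunDesign(run_id=run_id, markers=dict(PRIMERS), samples=samples, tag_map=tag_map)
        rd.validate()
        designs[run_id] = rd
    return designs, tags_fwd, tags_rev


# ---------------------------------------------------------------------------
# read simulation


def _apply_substitutions(seq: str, n_protected: int, rng, sub_rate: float) -> str:
    """Substitute bases beyond the first ``n_protected`` positions.

    Tags are protected: a tag error under exact-tag demultiplexing is
    plain read loss, which the switch rate already summarizes.
    """
    body_len = len(seq) - 2 * n_protected
    n_err = rng.binomial(body_len, sub_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(body_len, size=n_err, replace=False) + n_protected
    for pos in positions:
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[rng.integers(3)]
    return "".join(chars)


def simulate_reads(
    designs: dict[str, RunDesign],
    reference: list[RefTaxon],
    config: SimConfig,
    tags_fwd: list[str],
    tags_rev: list[str],
    rng=None,
) -> tuple[dict[str, list[tuple[str, str]]], GroundTruth]:
    """Emit merged tagged reads per run, plus the generating truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    by_species = {t.species: t for t in reference}
    conc = {sp: c for sp, c, _t1, _t2, _p in MOCK_PANEL}
    macro_pool = [t for t in reference if t.is_macro and t.species not in conc]
    truth = GroundTruth()

    # Planted diet per eDNA sample (habitat-compatible macrometazoans).
    all_samples: dict[str, SampleRecord] = {}
    for rd in designs.values():
        all_samples.update(rd.samples)
    for sid in sorted(all_samples):
        rec = all_samples[sid]
        if rec.category != EDNA:
            continue
        pool = [t for t in macro_pool if rec.habitat in t.habitats]
        n_prey = min(1 + int(rng.poisson(config.prey_mean)), len(pool))
        chosen = sorted(rng.choice(len(pool), size=n_prey, replace=False).tolist())
        abund = np.exp(rng.normal(0.0, config.abundance_sigma, size=n_prey))
        abund /= abund.sum()
        truth.sample_taxa[sid] = {
            pool[i].species: float(a) for i, a in zip(chosen, abund)
        }
        truth.planted[sid] = sorted(truth.sample_taxa[sid])
        # planted cross-habitat contaminants, one species per (sample, marker)
        for marker in sorted(PRIMERS):
            if rng.random() < config.contaminant_rate:
                bad = [
                    t
                    for t in macro_pool
                    if rec.habitat not in t.habitats and t.amplicons[marker] is not None
                ]
                if bad:
                    truth.contaminants[(sid, marker)] = bad[int(rng.integers(len(bad)))].species
    for sid, rec in sorted(all_samples.items()):
        if rec.category == MOCK:
            truth.planted[sid] = sorted(sp for sp, _ in rec.expected_taxa)
        elif rec.is_negative:
            truth.planted[sid] = []

    reads: dict[str, list[tuple[str, str]]] = {}
    for run_id in sorted(designs):
        rd = designs[run_id]
        pcr_tags = {
            (sample, marker, rep): (ftag, rtag)
            for (marker, ftag, rtag), (sample, rep) in rd.tag_map.items()
        }
        run_reads: list[tuple[str, str]] = []
        prov: dict[str, tuple[str, str, int, str, bool]] = {}
        n_read = 0
        for sample, marker, rep in rd.pcrs():
            rec = rd.samples[sample]
            composition: dict[str, int] = {}
            if rec.category == MOCK:
                taxa = [
                    sp for sp, _ in rec.expected_taxa if by_species[sp].amplicons[marker] is not None
                ]
                if taxa:
                    weights = np.array([conc[sp] for sp in taxa])
                    counts = rng.multinomial(config.reads_per_pcr, weights / weights.sum())
                    composition = {sp: int(c) for sp, c in zip(taxa, counts) if c}
            elif rec.category == EDNA:
                planted = truth.sample_taxa[sample]
                taxa = [sp for sp in sorted(planted) if by_species[sp].amplicons[marker] is not None]
                if taxa:
                    weights = np.array([planted[sp] for sp in taxa])
                    counts = rng.multinomial(config.reads_per_pcr, weights / weights.sum())
                    composition = {sp: int(c) for sp, c in zip(taxa, counts) if c}
                contaminant = truth.contaminants.get((sample, marker))
                if contaminant is not None:
                    n_cont = int(rng.poisson(config.contaminant_mean_reads))
                    if n_cont:
                        composition[contaminant] = composition.get(contaminant, 0) + n_cont
            else:  # negative control: contamination only
                n_cont = int(rng.poisson(config.neg_contam_mean))
                if n_cont:
                    pool = [t for t in reference if t.amplicons[marker] is not None]
                    sp = pool[int(rng.integers(len(pool)))].species
                    composition = {sp: n_cont}
            truth.per_pcr_composition[(run_id, sample, marker, rep)] = dict(composition)

            ftag, rtag = pcr_tags[(sample, marker, rep)]
            fwd_pat = PRIMERS[marker].fwd
            rev_pat = PRIMERS[marker].rev
            for sp in sorted(composition):
                insert = by_species[sp].amplicons[marker]
                for _ in range(composition[sp]):
                    n_read += 1
                    read_id = f"{run_id}:{n_read:07d}"
                    use_f, use_r = ftag, rtag
                    switched = False
                    if config.tag_switch_rate and rng.random() < config.tag_switch_rate:
                        switched = True
                        if rng.random() < 0.5:
                            others = [t for t in tags_fwd if t != ftag]
                            use_f = others[int(rng.integers(len(others)))]
                        else:
                            others = [t for t in tags_rev if t != rtag]
                            use_r = others[int(rng.integers(len(others)))]
                    body = (
                        realize_iupac(fwd_pat, rng)
                        + insert
                        + revcomp(realize_iupac(rev_pat, rng))
                    )
                    if config.sub_rate:
                        body = _apply_substitutions(body, 0, rng, config.sub_rate)
                    seq = use_f + body + revcomp(use_r)
                    if rng.random() < 0.5:
                        seq = revcomp(seq)
                    run_reads.append((read_id, seq))
                    prov[read_id] = (sample, marker, rep, sp, switched)
        reads[run_id] = run_reads
        truth.provenance[run_id] = prov

    # Detectable planted taxa: received reads in >= 2 replicates of some
    # marker (the replicate-consensus rule cannot validate anything else).
    rep_hits: dict[str, dict[tuple[str, str], int]] = {}
    for (_run, sample, marker, _rep), comp in truth.per_pcr_composition.items():
        per_sample = rep_hits.setdefault(sample, {})
        for sp, n in comp.items():
            if n > 0:
                per_sample[(sp, marker)] = per_sample.get((sp, marker), 0) + 1
    for sid, planted in truth.planted.items():
        hits = rep_hits.get(sid, {})
        truth.expected_items[sid] = sorted(
            sp
            for sp in planted
            if any(hits.get((sp, m), 0) >= 2 for m in PRIMERS)
        )
    return reads, truth


def simulate_run(config: SimConfig) -> SyntheticRun:
    """Generate a complete synthetic study (reference, design, reads)."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    designs, tags_fwd, tags_rev = generate_design(config, rng)
    reads, truth = simulate_reads(designs, reference, config, tags_fwd, tags_rev, rng)
    return SyntheticRun(config, reference, designs, tags_fwd, tags_rev, reads, truth)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced configuration for quick end-to-end exercises."""
    base = SimConfig(
        seed=seed,
        n_taxa=16,
        reads_per_pcr=150,
        n_edna_samples=6,
        samples_per_run=24,
    )
    return replace(base, **overrides)
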