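"""Two-condition multi-class count simulator with planted ceRNA structure.

The generator emulates a stem-cell-treatment vs. disease contrast profiled
across four RNA classes (mRNA, lncRNA, circRNA, miRNA).  Counts are
negative-binomial, NB(mu, alpha) with variance mu + alpha*mu^2, around
log-uniform baseline means; a configurable fraction of each class carries a
group effect of fixed |log2FC|.

Planted ceRNA triplets provide ground truth for the network stages.  Each
triplet is one sponge (a lncRNA or circRNA), ``shared_mirnas_per_triplet``
dedicated miRNAs, and one mRNA.  All members are differentially expressed
(sponge and mRNA in the triplet's direction, miRNAs opposite), and a latent
per-sample factor is added on the log2 scale to sponge and mRNA and
subtracted from the miRNAs, so that pooled across samples the sponge-mRNA
pair is strongly positively correlated and every miRNA-target pair strongly
negatively - the structure the downstream Pearson filters look for.

Sequences give the seed scanner ground truth.  Backgrounds are generated
free of the CpG dinucleotide, and planted miRNAs are drawn so that their
6mer target pattern contains CG; a background can therefore never contain a
seed site for a planted miRNA, and the only sites are the ones explicitly
embedded (and re-verified) at recorded positions.  The CpG-free background
is a caricature of the CpG suppression seen in vertebrate genomes; it is a
device for clean ground truth, not a sequence model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import RNA_CLASSES, CountMatrix
from .mre import scan_sites, seed_patterns

TARGET_CLASSES = ("mRNA", "lncRNA", "circRNA")


@dataclass
class TripletTruth:
    """One planted sponge - shared-miRNAs - mRNA triplet."""

    ce_id: str
    ce_class: str  # lncRNA or circRNA
    mirna_ids: list[str]
    mrna_id: str
    direction: str  # up|down: DE direction of sponge and mRNA (treated vs ref)

    def __post_init__(self) -> None:
        if self.ce_class not in ("lncRNA", "circRNA"):
            raise ValueError("sponge must be a lncRNA or circRNA")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("triplet miRNA ids must be distinct")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be up or down")


@dataclass
class SyntheticDataset:
    """Counts, labels, sequences and the planted ground truth."""

    config: SimConfig
    counts: dict[str, CountMatrix]
    groups: pd.Series                  # sample_id -> group name
    mapped_reads: pd.Series            # per-sample mapped-read totals
    truth_de: pd.DataFrame             # feature_id, class, is_de, true_log2fc, planted
    truth_triplets: list[TripletTruth]
    sequences: dict[str, str] = field(default_factory=dict)
    truth_sites: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = {c: set(self.counts[c].values.index) for c in self.counts}
        for t in self.truth_triplets:
            if t.ce_id not in cols[t.ce_class]:
                raise ValueError(f"unknown sponge {t.ce_id}")
            if t.mrna_id not in cols["mRNA"]:
                raise ValueError(f"unknown mRNA {t.mrna_id}")
            missing = set(t.mirna_ids) - cols["miRNA"]
            if missing:
                raise ValueError(f"unknown miRNAs {sorted(missing)}")
        samp = list(self.groups.index)
        for cm in self.counts.values():
            if cm.sample_ids != samp:
                raise ValueError("matrices must share the sample ordering")


def _feature_ids(feature_class: str, n: int) -> list[str]:
    prefix = {"mRNA": "gene", "lncRNA": "lnc", "circRNA": "circ",
              "miRNA": "mir"}[feature_class]
    return [f"{prefix}_{i:04d}" for i in range(1, n + 1)]


def _pick_de(rng: np.random.Generator, n: int, frac: float,
             planted_idx: np.ndarray) -> np.ndarray:
    """Boolean DE mask covering planted features plus random fill."""
    mask = np.zeros(n, dtype=bool)
    mask[planted_idx] = True
    n_target = int(round(frac * n))
    extra = n_target - mask.sum()
    if extra > 0:
        free = np.flatnonzero(~mask)
        mask[rng.choice(free, size=min(extra, free.size), replace=False)] = True
    return mask


def simulate_experiment(config: SimConfig) -> SyntheticDataset:
    """Draw one synthetic experiment; identical config => identical output."""
    rng = np.random.default_rng(config.rng_seed)
    npg = config.samples_per_group
    ref, treat = config.group_names
    samples = [f"{g}_{i + 1}" for g in (ref, treat) for i in range(npg)]
    groups = pd.Series([ref] * npg + [treat] * npg,
                       index=pd.Index(samples, name="sample_id"), name="group")
    treat_mask = (groups == treat).to_numpy()

    ids = {c: _feature_ids(c, config.n_features(c)) for c in RNA_CLASSES}

    # ---- plant triplets --------------------------------------------------
    k = config.shared_mirnas_per_triplet
    n_trip = config.n_planted_triplets
    n_lnc_trip = (n_trip + 1) // 2
    n_circ_trip = n_trip - n_lnc_trip
    n_shared = min(config.n_shared_mrnas, n_lnc_trip, n_circ_trip)
    n_mrna_needed = n_lnc_trip + n_circ_trip - n_shared
    if n_mrna_needed > config.n_mrna:
        raise ValueError("not enough mRNAs for the requested triplets")
    if n_lnc_trip > config.n_lncrna or n_circ_trip > config.n_circrna:
        raise ValueError("not enough sponges for the requested triplets")

    mrna_pool = list(rng.permutation(ids["mRNA"])[:n_mrna_needed])
    lnc_pool = list(rng.permutation(ids["lncRNA"])[:n_lnc_trip])
    circ_pool = list(rng.permutation(ids["circRNA"])[:n_circ_trip])
    mir_pool = list(rng.permutation(ids["miRNA"])[:n_trip * k])

    triplets: list[TripletTruth] = []
    for i in range(n_lnc_trip):
        triplets.append(TripletTruth(
            ce_id=lnc_pool[i], ce_class="lncRNA",
            mirna_ids=mir_pool[i * k:(i + 1) * k],
            mrna_id=mrna_pool[i],
            direction="up" if i % 2 == 0 else "down"))
    for j in range(n_circ_trip):
        # the first n_shared circRNA triplets reuse the lncRNA triplets' mRNAs
        mrna = mrna_pool[j] if j < n_shared else mrna_pool[n_lnc_trip + j - n_shared]
        direction = ("up" if j % 2 == 0 else "down") if j >= n_shared \
            else triplets[j].direction
        triplets.append(TripletTruth(
            ce_id=circ_pool[j], ce_class="circRNA",
            mirna_ids=mir_pool[(n_lnc_trip + j) * k:(n_lnc_trip + j + 1) * k],
            mrna_id=mrna, direction=direction))

    # Triplet pairs sharing an mRNA share one latent factor; otherwise the
    # shared mRNA would carry two independent factors and its correlation
    # with either sponge (and with each miRNA) would be diluted below the
    # planted-structure thresholds.
    factor_idx = list(range(n_trip))
    for j in range(n_shared):
        factor_idx[n_lnc_trip + j] = j

    # per-feature planted sign of the group effect (treated vs reference)
    planted_sign: dict[str, float] = {}
    trip_members: dict[str, set[tuple[int, float]]] = {}  # id -> (factor, coupling)
    for ti, t in enumerate(triplets):
        s = 1.0 if t.direction == "up" else -1.0
        for fid in (t.ce_id, t.mrna_id):
            planted_sign[fid] = s
            trip_members.setdefault(fid, set()).add((factor_idx[ti], 1.0))
        for mid in t.mirna_ids:
            planted_sign[mid] = -s
            trip_members.setdefault(mid, set()).add((factor_idx[ti], -1.0))

    # Latent per-sample sponge factor, one per triplet (log2 scale),
    # centered within each group: the factor creates co-variation without
    # perturbing the group means, so the planted log2FC stays exactly
    # de_log2fc_magnitude in expectation.
    if n_trip:
        latent = rng.normal(0.0, 1.0, size=(n_trip, 2 * npg))
        for mask in (~treat_mask, treat_mask):
            latent[:, mask] -= latent[:, mask].mean(axis=1, keepdims=True)
    else:
        latent = None

    counts: dict[str, CountMatrix] = {}
    truth_rows = []
    lfc = config.de_log2fc_magnitude
    lo, hi = config.nb_mean_range
    for cls in RNA_CLASSES:
        n = config.n_features(cls)
        fids = ids[cls]
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        planted_idx = np.array(
            [i for i, f in enumerate(fids) if f in planted_sign], dtype=int)
        if planted_idx.size:
            # sponge crosstalk is only identifiable for abundant transcripts;
            # planted members draw their baseline from the upper half of the
            # mean range so the coupling is not drowned by counting noise
            base[planted_idx] = np.exp(rng.uniform(
                np.log(max(lo, hi / 2.0)), np.log(hi), size=planted_idx.size))
        de_mask = _pick_de(rng, n, config.de_fraction_for(cls), planted_idx)
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        for i in planted_idx:
            sign[i] = planted_sign[fids[i]]
        true_l2fc = np.where(de_mask, sign * lfc, 0.0)

        log2mu = np.tile(np.log2(base)[:, None], (1, 2 * npg))
        log2mu[:, treat_mask] += true_l2fc[:, None]
        if n_trip:
            for i in planted_idx:
                for fi, coup in trip_members[fids[i]]:
                    log2mu[i] += coup * config.sponge_strength * latent[fi]
        if config.noise_sd > 0:
            log2mu += rng.normal(0.0, config.noise_sd, size=log2mu.shape)

        mu = np.power(2.0, log2mu)
        r = 1.0 / config.nb_dispersion
        vals = rng.negative_binomial(r, r / (r + mu))
        if cls in ("mRNA", "lncRNA"):
            lengths = pd.Series(rng.integers(300, 3001, size=n), index=fids)
        elif cls == "miRNA":
            lengths = pd.Series(config.mirna_length, index=fids)
        else:
            lengths = None  # circRNA BSJ counts: no effective length
        counts[cls] = CountMatrix(
            pd.DataFrame(vals, index=pd.Index(fids, name="feature_id"),
                         columns=samples),
            cls, lengths)
        truth_rows.append(pd.DataFrame(
            {"feature_id": fids, "feature_class": cls, "is_de": de_mask,
             "true_log2fc": true_l2fc,
             "planted": np.isin(np.arange(n), planted_idx)}))

    # Library depth: every sample is simulated at the same expected scale,
    # so mapped totals are a constant with a few percent of prep-to-prep
    # jitter, independent of the treatment (sequencing depth is a property
    # of the library, not of the biology).
    mapped = pd.Series(
        np.round(2e7 * np.exp(rng.normal(0.0, 0.02, size=2 * npg))).astype(
            np.int64),
        index=pd.Index(samples, name="sample_id"), name="mapped_reads")

    dataset = SyntheticDataset(
        config=config, counts=counts, groups=groups, mapped_reads=mapped,
        truth_de=pd.concat(truth_rows, ignore_index=True),
        truth_triplets=triplets)
    generate_target_sequences(dataset, config.site_class, rng=rng)
    return dataset


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

_NO_CG_AFTER_C = "ACU"
_ALL = "ACGU"


def _background(rng: np.random.Generator, length: int) -> list[str]:
    """CpG-dinucleotide-free random RNA sequence (as a char list)."""
    out: list[str] = []
    prev = ""
    for _ in range(length):
        pool = _NO_CG_AFTER_C if prev == "C" else _ALL
        c = pool[rng.integers(len(pool))]
        out.append(c)
        prev = c
    return out


def _site_pattern(mirna_seq: str, site_class: str) -> str:
    return seed_patterns(mirna_seq)[site_class]


def _planted_mirna_seq(rng: np.random.Generator, length: int,
                       used_patterns: list[tuple[str, str]]) -> str:
    """Random miRNA whose 6mer target pattern contains CG and is unique.

    Also rejects seeds whose 6mer pattern is contained in any other planted
    miRNA's 8mer site pattern (or vice versa): such a containment would
    make one planted miRNA match inside another's embedded site on every
    draw, so no clean target could ever be generated.
    """
    while True:
        seq = "".join(_ALL[i] for i in rng.integers(0, 4, size=length))
        pats = seed_patterns(seq)
        p6, p8 = pats["6mer"], pats["8mer"]
        if "CG" not in p6:
            continue
        if any(p6 in o8 or o6 in p8 for o6, o8 in used_patterns):
            continue
        used_patterns.append((p6, p8))
        return seq


def _embed_sites(rng: np.random.Generator, length: int,
                 mirna_seqs: list[str], site_class: str,
                 other_patterns: list[tuple[str, str]],
                 max_tries: int = 200) -> tuple[str, list[tuple[int, int]]]:
    """Background with one site per miRNA embedded at recorded positions.

    Retries until scanning each of the sequence's own miRNAs recovers
    exactly the recorded sites and no other planted miRNA matches at all
    (junction artefacts are possible in principle, hence the verification).
    """
    patterns = [_site_pattern(m, site_class) for m in mirna_seqs]
    k = len(patterns)
    block = length // k
    if block < max(len(p) for p in patterns) + 4:
        raise ValueError("target sequence too short for the requested sites")
    for _ in range(max_tries):
        seq = _background(rng, length)
        spans: list[tuple[int, int]] = []
        for i, pat in enumerate(patterns):
            lo = i * block + 1
            hi = min((i + 1) * block, length) - len(pat) - 1
            p = int(rng.integers(lo, hi + 1))
            seq[p:p + len(pat)] = list(pat)
            spans.append((p, p + len(pat)))
        s = "".join(seq)
        ok = True
        for (start, end), m in zip(spans, mirna_seqs):
            found = scan_sites(m, s)
            if [(f.start, f.end, f.site_class) for f in found] != \
                    [(start, end, site_class)]:
                ok = False
                break
        if ok:
            for _mid, m in other_patterns:
                if scan_sites(m, s):
                    ok = False
                    break
        if ok:
            return s, spans
    raise RuntimeError("could not embed clean sites; sequence too constrained")


def generate_target_sequences(dataset: SyntheticDataset, site_class: str,
                              rng: np.random.Generator | None = None) -> dict[str, str]:
    """Populate ``dataset.sequences`` and ``dataset.truth_sites``.

    Planted miRNAs get seed-constrained sequences; every planted target
    (sponge and mRNA of each triplet) gets one embedded ``site_class`` site
    per truth miRNA at a recorded position; all remaining mRNA/lncRNA/
    circRNA sequences and non-planted miRNAs are site-free backgrounds with
    respect to every planted miRNA.  Returns the full sequence map.
    """
    cfg = dataset.config
    if site_class not in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
        raise ValueError(f"unknown site class {site_class!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 104729)

    seqs: dict[str, str] = {}
    used_patterns: list[tuple[str, str]] = []
    planted_mirnas: dict[str, str] = {}
    for t in dataset.truth_triplets:
        for mid in t.mirna_ids:
            if mid not in planted_mirnas:
                planted_mirnas[mid] = _planted_mirna_seq(
                    rng, cfg.mirna_length, used_patterns)
    seqs.update(planted_mirnas)
    for mid in dataset.counts["miRNA"].values.index:
        if mid not in seqs:
            seqs[mid] = "".join(_ALL[i] for i in
                                rng.integers(0, 4, size=cfg.mirna_length))

    # which miRNAs hit which target
    target_mirnas: dict[str, list[str]] = {}
    for t in dataset.truth_triplets:
        for tid in (t.ce_id, t.mrna_id):
            target_mirnas.setdefault(tid, [])
            target_mirnas[tid].extend(
                m for m in t.mirna_ids if m not in target_mirnas[tid])

    site_rows = []
    all_planted = list(planted_mirnas.items())
    for tid, mids in target_mirnas.items():
        others = [(mid, planted_mirnas[mid]) for mid in planted_mirnas
                  if mid not in mids]
        s, spans = _embed_sites(rng, cfg.target_seq_length,
                                [planted_mirnas[m] for m in mids],
                                site_class, others)
        seqs[tid] = s
        for mid, (start, end) in zip(mids, spans):
            site_rows.append({"mirna_id": mid, "target_id": tid,
                              "start": start, "end": end,
                              "site_class": site_class})

    for cls in TARGET_CLASSES:
        for fid in dataset.counts[cls].values.index:
            if fid not in seqs:
                seqs[fid] = "".join(_background(rng, cfg.target_seq_length))

    dataset.sequences = seqs
    dataset.truth_sites = pd.DataFrame(
        site_rows, columns=["mirna_id", "target_id", "start", "end",
                            "site_class"])
    return seqs


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> list[Path]:
    """Write the dataset as plain-text fixture files; returns the manifest.

    One counts TSV per RNA class, a sample sheet, mapped-read totals, a
    FASTA with every sequence, truth tables, and a GMT whose sets are built
    from the planted truth.  Files round-trip through ``cernapipe.io``.
    """
    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    for cls, cm in dataset.counts.items():
        path = directory / f"counts_{cls}.tsv"
        cio.write_count_matrix(cm, path)
        manifest.append(path)

    path = directory / "samples.tsv"
    dataset.groups.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False)
    manifest.append(path)

    path = directory / "mapped_reads.tsv"
    dataset.mapped_reads.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False)
    manifest.append(path)

    path = directory / "sequences.fasta"
    cio.write_fasta(dataset.sequences, path)
    manifest.append(path)

    path = directory / "truth_de.tsv"
    dataset.truth_de.to_csv(path, sep="\t", index=False)
    manifest.append(path)

    path = directory / "truth_triplets.tsv"
    rows = [{"ce_id": t.ce_id, "ce_class": t.ce_class,
             "mirna_ids": ",".join(t.mirna_ids), "mrna_id": t.mrna_id,
             "direction": t.direction} for t in dataset.truth_triplets]
    pd.DataFrame(rows, columns=["ce_id", "ce_class", "mirna_ids", "mrna_id",
                                "direction"]).to_csv(path, sep="\t",
                                                     index=False)
    manifest.append(path)

    path = directory / "truth_sites.tsv"
    sites = dataset.truth_sites if dataset.truth_sites is not None else \
        pd.DataFrame(columns=["mirna_id", "target_id", "start", "end",
                              "site_class"])
    sites.to_csv(path, sep="\t", index=False)
    manifest.append(path)

    path = directory / "gene_sets.gmt"
    planted_mrnas = sorted({t.mrna_id for t in dataset.truth_triplets})
    de_up = sorted(dataset.truth_de.query(
        "feature_class == 'mRNA' and is_de and true_log2fc > 0")["feature_id"])
    de_down = sorted(dataset.truth_de.query(
        "feature_class == 'mRNA' and is_de and true_log2fc < 0")["feature_id"])
    sets = [("planted_mrnas", "mRNAs of planted ceRNA triplets", planted_mrnas),
            ("de_up_mrnas", "mRNAs simulated upregulated", de_up),
            ("de_down_mrnas", "mRNAs simulated downregulated", de_down)]
    cio.write_gmt([s for s in sets if s[2]], path)
    manifest.append(path)

    return manifest


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Inverse of :func:`write_fixture` (config defaults are not restored)."""
    from . import io as cio

    directory = Path(directory)
    counts = {cls: cio.read_count_matrix(directory / f"counts_{cls}.tsv")
              for cls in RNA_CLASSES}
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    groups = pd.Series(samples["group"].to_numpy(),
                       index=pd.Index(samples["sample_id"], name="sample_id"),
                       name="group")
    mapped = pd.read_csv(directory / "mapped_reads.tsv", sep="\t")
    mapped = pd.Series(mapped["mapped_reads"].to_numpy(),
                       index=pd.Index(mapped["sample_id"], name="sample_id"),
                       name="mapped_reads")
    truth_de = pd.read_csv(directory / "truth_de.tsv", sep="\t")
    trip_df = pd.read_csv(directory / "truth_triplets.tsv", sep="\t")
    triplets = [TripletTruth(r.ce_id, r.ce_class, r.mirna_ids.split(","),
                             r.mrna_id, r.direction)
                for r in trip_df.itertuples()]
    sites = pd.read_csv(directory / "truth_sites.tsv", sep="\t")
    seqs = cio.read_fasta(directory / "sequences.fasta")
    groups_levels = list(pd.unique(groups))
    cfg = SimConfig(samples_per_group=max(1, len(groups) // 2),
                    n_mrna=counts["mRNA"].n_features,
                    n_lncrna=counts["lncRNA"].n_features,
                    n_circrna=counts["circRNA"].n_features,
                    n_mirna=counts["miRNA"].n_features,
                    n_planted_triplets=len(triplets),
                    shared_mirnas_per_triplet=max(
                        [3] + [len(t.mirna_ids) for t in triplets]),
                    group_names=tuple(groups_levels) if len(groups_levels) == 2
                    else ("A", "B"))
    return SyntheticDataset(config=cfg, counts=counts, groups=groups,
                            mapped_reads=mapped, truth_de=truth_de,
                            truth_triplets=triplets, sequences=seqs,
                            truth_sites=sites)
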