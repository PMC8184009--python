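"""Position-weight-matrix splice-site models and branchpoint discovery.

Donor and acceptor models are log-odds PWMs trained on annotated splice
sites and scored on a min-max normalized [0,1] scale, a structural
analog of neural-network splice-site scores: thresholds such as 0.75
("strong site") are comparable in spirit but not numerically identical
to any external scorer.

Window geometry follows the splice-site consensus: donors are scored on
3 exonic + 6 intronic nt (AG|GTAAGT context), acceptors on 14 intronic
+ 3 exonic nt (polypyrimidine tract, YAG|G). The branchpoint motif is
derived de novo from windows 15-45 nt upstream of annotated acceptors
with a one-occurrence-per-sequence EM motif finder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 14
ACCEPTOR_EXONIC = 3
BP_WINDOW = (15, 45)  # nt upstream of the acceptor boundary


def encode(seq: str) -> np.ndarray:
    """Integer-encode an ACGT string; any other symbol becomes -1."""
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)


@dataclass
class PositionWeightMatrix:
    """Log-odds matrix over A,C,G,T with window geometry and score bounds."""

    kind: str                    # donor | acceptor | branchpoint
    log_odds: np.ndarray         # width x 4
    background: np.ndarray       # length-4 frequencies
    exonic_up: int = 0
    exonic_down: int = 0
    frequencies: np.ndarray | None = None  # width x 4, pre-log-odds
    n_training: int = 0
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.score_min = float(self.log_odds.min(axis=1).sum())
        self.score_max = float(self.log_odds.max(axis=1).sum())

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information (bits) relative to the background."""
        f = self.frequencies
        if f is None:
            raise ValueError("PWM built without frequencies")
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f / self.background), 0.0)
        return terms.sum(axis=1)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#kind\t{self.kind}\n#width\t{self.width}\n")
            fh.write(f"#exonic_up\t{self.exonic_up}\n#exonic_down\t{self.exonic_down}\n")
            fh.write("#background\t" + "\t".join(f"{x:.6g}" for x in self.background) + "\n")
            fh.write(f"#n_training\t{self.n_training}\n")
            fh.write("pos\t" + "\t".join(BASES) + "\n")
            for i, row in enumerate(self.log_odds):
                fh.write(f"{i}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "PositionWeightMatrix":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].rstrip("\n").partition("\t")
                    meta[key] = val
                elif not line.startswith("pos"):
                    rows.append([float(x) for x in line.split("\t")[1:5]])
        return cls(
            kind=meta["kind"],
            log_odds=np.array(rows),
            background=np.array([float(x) for x in meta["background"].split("\t")]),
            exonic_up=int(meta.get("exonic_up", 0)),
            exonic_down=int(meta.get("exonic_down", 0)),
            n_training=int(meta.get("n_training", 0)),
        )


@dataclass(frozen=True)
class SpliceSiteScore:
    raw: float
    normalized: float
    missing: bool = False

    @staticmethod
    def na() -> "SpliceSiteScore":
        return SpliceSiteScore(raw=float("nan"), normalized=float("nan"), missing=True)


def train_pwm(
    windows: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    kind: str = "donor",
    exonic_up: int = 0,
    exonic_down: int = 0,
) -> PositionWeightMatrix:
    """Train a log-odds PWM from equal-length windows.

    Windows containing N (or other non-ACGT symbols) are dropped; fewer
    than 10 usable windows is an error. ``background`` defaults to
    uniform base frequencies, which guarantees that the column-wise
    most-frequent sequence attains normalized score 1; callers modelling
    genomic context (the annotation-trained splice models) pass the
    pooled base frequencies of their training windows instead.
    """
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"windows of unequal length: {sorted(widths)}")
    enc = [e for e in (encode(w) for w in windows) if (e >= 0).all()]
    n_dropped = len(windows) - len(enc)
    if len(enc) < 10:
        raise ValueError(f"only {len(enc)} usable windows (<10); {n_dropped} dropped")
    mat = np.stack(enc)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)], axis=1).astype(float)
    freqs = (counts + pseudocount) / (mat.shape[0] + 4 * pseudocount)
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    log_odds = np.log2(freqs / background)
    return PositionWeightMatrix(
        kind=kind, log_odds=log_odds, background=background,
        exonic_up=exonic_up, exonic_down=exonic_down,
        frequencies=freqs, n_training=mat.shape[0],
    )


def score_site(pwm: PositionWeightMatrix, window: str) -> SpliceSiteScore:
    """Score one window; normalized = (raw - min)/(max - min) in [0,1]."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    e = encode(window)
    if (e < 0).any():
        return SpliceSiteScore.na()
    raw = float(pwm.log_odds[np.arange(pwm.width), e].sum())
    span = pwm.score_max - pwm.score_min
    norm = (raw - pwm.score_min) / span if span > 0 else 0.0
    return SpliceSiteScore(raw=raw, normalized=float(np.clip(norm, 0.0, 1.0)))


def donor_window(seq_source, chrom: str, strand: str, boundary: int) -> tuple[str, bool]:
    """Genomic donor window (3 exonic + 6 intronic) in sense orientation."""
    from crypticsplice.annotation_io import extract_window
    return extract_window(seq_source, chrom, strand, boundary, DONOR_EXONIC, DONOR_INTRONIC)


def acceptor_window(seq_source, chrom: str, strand: str, boundary: int) -> tuple[str, bool]:
    """Genomic acceptor window (14 intronic + 3 exonic) in sense orientation."""
    from crypticsplice.annotation_io import extract_window
    return extract_window(seq_source, chrom, strand, boundary, ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC)


def train_splice_models(ann, g, seed: int = 0) -> tuple[PositionWeightMatrix, PositionWeightMatrix]:
    """Train donor and acceptor PWMs from all annotated splice sites.

    Deterministic given the annotation (sites are iterated in sorted
    order; ``seed`` is reserved for optional subsampling and does not
    affect the default full-data fit). Requires >= 100 annotated introns.
    """
    if len(ann.annotated_junctions) < 100:
        raise ValueError(
            f"only {len(ann.annotated_junctions)} annotated introns (<100)")
    donor_wins, acceptor_wins = [], []
    for chrom, strand, pos in sorted(ann.annotated_donors):
        w, clipped = donor_window(g, chrom, strand, pos)
        if not clipped:
            donor_wins.append(w)
    for chrom, strand, pos in sorted(ann.annotated_acceptors):
        w, clipped = acceptor_window(g, chrom, strand, pos)
        if not clipped:
            acceptor_wins.append(w)

    def _pooled_background(wins: list[str]) -> np.ndarray:
        arr = np.concatenate([encode(w) for w in wins])
        counts = np.bincount(arr[arr >= 0], minlength=4).astype(float)
        return (counts + 1.0) / (counts.sum() + 4.0)

    donor = train_pwm(donor_wins, background=_pooled_background(donor_wins),
                      kind="donor", exonic_up=DONOR_EXONIC, exonic_down=0)
    acceptor = train_pwm(acceptor_wins, background=_pooled_background(acceptor_wins),
                         kind="acceptor", exonic_up=0, exonic_down=ACCEPTOR_EXONIC)
    return donor, acceptor


# ---------------------------------------------------------------------------
# One-occurrence-per-sequence EM motif finder (branchpoint discovery)
# ---------------------------------------------------------------------------

def _oops_em(
    mats: np.ndarray, width: int, rng: np.random.Generator,
    max_iter: int = 200, tol: float = 1e-6, pseudocount: float = 1.0,
    init_freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run EM from one random start; returns (freqs, objective, trajectory).

    Model: each sequence carries exactly one motif occurrence at a
    uniform random offset; remaining positions follow a 0-order
    background estimated from all input bases. The reported objective is
    the penalized log-likelihood (data log-likelihood plus the Dirichlet
    log-prior implied by the pseudocount), which EM theory guarantees to
    be non-decreasing across iterations for this E/M pair.
    """
    n, L = mats.shape
    n_pos = L - width + 1
    base_counts = np.bincount(mats.ravel(), minlength=4).astype(float)
    bg = (base_counts + 1.0) / (base_counts.sum() + 4.0)
    log_bg = np.log(bg)
    # per-sequence constant: log background probability of the full sequence
    log_pbg_full = log_bg[mats].sum(axis=1)

    if init_freqs is not None:
        freqs = np.asarray(init_freqs, dtype=float)
    else:
        # init: frequencies from a randomly chosen subwindow per
        # sequence, heavily smoothed so EM can move
        offs = rng.integers(0, n_pos, size=n)
        sub = np.stack([mats[i, o:o + width] for i, o in enumerate(offs)])
        counts = np.stack([(sub == b).sum(axis=0) for b in range(4)], axis=1).astype(float)
        freqs = (counts + 4.0) / (n + 16.0)

    # windows[i, p, k] = base at offset p+k of sequence i
    idx = np.arange(n_pos)[:, None] + np.arange(width)[None, :]
    windows = mats[:, idx]  # n x n_pos x width
    log_bg_win = log_bg[windows].sum(axis=2)  # n x n_pos

    prev_obj = -np.inf
    trajectory: list[float] = []
    for _ in range(max_iter):
        log_motif = np.log(freqs)
        log_ratio = log_motif[np.arange(width)[None, None, :], windows] \
            .sum(axis=2) - log_bg_win  # n x n_pos
        m = log_ratio.max(axis=1, keepdims=True)
        w = np.exp(log_ratio - m)
        z = w.sum(axis=1, keepdims=True)
        post = w / z
        ll = float((log_pbg_full + m[:, 0] + np.log(z[:, 0]) - np.log(n_pos)).sum())
        obj = ll + pseudocount * float(np.log(freqs).sum())
        trajectory.append(obj)
        if obj - prev_obj < tol and np.isfinite(prev_obj):
            break
        prev_obj = obj
        # M-step: expected base counts per motif column
        counts = np.zeros((width, 4))
        for b in range(4):
            counts[:, b] = (post[:, :, None] * (windows == b)).sum(axis=(0, 1))
        freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return freqs, trajectory[-1], trajectory


def discover_motif(
    windows: list[str], motif_width: int = 7, seed: int = 0,
    n_restarts: int = 5, max_iter: int = 200, tol: float = 1e-6,
    return_trajectories: bool = False,
):
    """One-occurrence-per-sequence EM motif discovery.

    Runs ``n_restarts`` random restarts, then refines the best solution
    against its +/-1 column-shifted phases (a standard guard against the
    phase ambiguity of one-occurrence-per-sequence models), returning
    the PWM of the highest-objective run (and, optionally, the
    per-run objective trajectories, each non-decreasing by EM
    construction).
    """
    enc = [e for e in (encode(w) for w in windows) if (e >= 0).all()
           and len(e) >= motif_width]
    if not enc:
        raise ValueError("no usable windows for motif discovery")
    L = min(len(e) for e in enc)
    mats = np.stack([e[:L] for e in enc])
    rng = np.random.default_rng(seed)
    best = None
    trajectories = []
    for _ in range(n_restarts):
        freqs, ll, traj = _oops_em(mats, motif_width, rng, max_iter=max_iter, tol=tol)
        trajectories.append(traj)
        if best is None or ll > best[1]:
            best = (freqs, ll)
    # phase refinement: restart EM from the +/-1-shifted best motif and
    # keep whichever phase ends with the higher objective
    uniform = np.full((1, 4), 0.25)
    for shifted in (np.vstack([uniform, best[0][:-1]]),
                    np.vstack([best[0][1:], uniform])):
        freqs, ll, traj = _oops_em(mats, motif_width, rng, max_iter=max_iter,
                                   tol=tol, init_freqs=shifted)
        trajectories.append(traj)
        if ll > best[1]:
            best = (freqs, ll)
    freqs, ll = best
    base_counts = np.bincount(mats.ravel(), minlength=4).astype(float)
    bg = (base_counts + 1.0) / (base_counts.sum() + 4.0)
    pwm = PositionWeightMatrix(
        kind="branchpoint", log_odds=np.log2(freqs / bg), background=bg,
        frequencies=freqs, n_training=len(enc),
    )
    if return_trajectories:
        return pwm, ll, trajectories
    return pwm


def derive_branchpoint_pwm(
    ann, g, n_introns: int = 10000,
    window: tuple[int, int] = BP_WINDOW, motif_width: int = 7, seed: int = 0,
) -> PositionWeightMatrix:
    """Derive a branchpoint PWM from intronic sequence upstream of
    annotated acceptors.

    Samples up to ``n_introns`` annotated introns (without replacement),
    extracts the ``window=[15,45]`` nt region upstream of each 3' splice
    site (intron side), and runs the EM motif finder. Introns shorter
    than ``window[1] + motif_width`` nt are skipped.
    """
    lo, up = window
    rng = np.random.default_rng(seed)
    juncs = sorted(ann.annotated_junctions)
    usable = [j for j in juncs if (j[3] - j[2]) >= up + motif_width]
    if len(usable) < min(1000, max(1, len(juncs))) and len(usable) < 50:
        raise ValueError(f"only {len(usable)} introns long enough for BP windows")
    if len(usable) > n_introns:
        pick = rng.choice(len(usable), size=n_introns, replace=False)
        usable = [usable[i] for i in sorted(pick)]
    from crypticsplice.annotation_io import extract_window
    wins = []
    for chrom, strand, istart, iend in usable:
        acc_boundary = istart if strand == "-" else iend
        seq, clipped = extract_window(g, chrom, strand, acc_boundary, up, 0)
        if clipped:
            continue
        wins.append(seq[: up - lo + 1])  # positions -up .. -lo inclusive
    return discover_motif(wins, motif_width=motif_width,
                          seed=int(rng.integers(0, 2**31 - 1)))


def scan_branchpoint(
    pwm: PositionWeightMatrix, region: str, min_match: float = 0.75,
) -> tuple[list[tuple[int, float]], tuple[int, float]]:
    """Scan a region with the branchpoint PWM.

    Returns ``(hits, best)`` where ``hits`` is every ``(offset,
    match_fraction)`` with normalized score >= ``min_match`` and ``best``
    is the top-scoring offset regardless of threshold.
    """
    if len(region) < pwm.width:
        raise ValueError(f"region length {len(region)} < PWM width {pwm.width}")
    hits, best = [], None
    for off in range(len(region) - pwm.width + 1):
        s = score_site(pwm, region[off:off + pwm.width])
        if s.missing:
            continue
        if best is None or s.normalized > best[1]:
            best = (off, s.normalized)
        if s.normalized >= min_match:
            hits.append((off, s.normalized))
    if best is None:
        best = (-1, float("nan"))
    return hits, best


def nucleotide_content(windows: list[str]) -> np.ndarray:
    """Position x base (A,C,G,T) frequency matrix for logo plotting.

    N (and any non-ACGT symbol) is excluded from the per-column
    denominator. Columns with data sum to 1.
    """
    if not windows:
        raise ValueError("empty window list")
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"windows of unequal length: {sorted(widths)}")
    mat = np.stack([encode(w) for w in windows])
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)], axis=1).astype(float)
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, counts / denom, 0.0)
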