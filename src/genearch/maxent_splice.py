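"""Maximum-entropy splice-site strength models.

A splice site's strength is the log2-odds (bits) of its fixed-width window
under a *signal* distribution, fitted to annotated-site windows, against a
*background* distribution fitted to decoy windows that carry the obligate
dinucleotide (GT for donors, AG for acceptors) at the correct offset but
are not annotated sites.

Both distributions are maximum-entropy models subject to marginal
constraints: among all distributions whose marginals over the chosen
position subsets match the (pseudocounted) empirical marginals, the one of
maximal entropy is found by iterative proportional fitting (a member of the
generalized-iterative-scaling family). Small windows (the 9-nt donor) are
fitted densely over 4^k outcomes; long windows (the 23-nt acceptor) are
factorized into overlapping fragments whose conditional chain yields an
exactly normalized joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_model import (
    ACCEPTOR_EXONIC,
    ACCEPTOR_INTRONIC,
    ACCEPTOR_WIDTH,
    DONOR_EXONIC,
    DONOR_INTRONIC,
    DONOR_WIDTH,
    IntronRecord,
    TranscriptModel,
    annotated_site_positions,
    premrna_sequence,
)
from .genome import GenomeSequence

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

QUARTILE_LABELS = ("weak", "moderately weak", "moderately strong", "strong")

DENSE_WIDTH_LIMIT = 12  # beyond this, use the factorized fit


def encode(window: str) -> tuple[int, ...]:
    try:
        return tuple(_BASE_INDEX[b] for b in window)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in window {window!r}") from exc


@dataclass(frozen=True)
class MarginalConstraintSet:
    """Position subsets whose joint marginals the fit must match."""

    k: int
    subsets: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        seen = set()
        covered: set[int] = set()
        for s in self.subsets:
            t = tuple(sorted(s))
            if t != tuple(s):
                raise ValueError(f"constraint subset {s} must be sorted")
            if t in seen:
                raise ValueError(f"duplicate constraint subset {s}")
            seen.add(t)
            if any(p < 0 or p >= self.k for p in s):
                raise ValueError(f"constraint position out of range in {s}")
            covered.update(s)
        if covered != set(range(self.k)):
            raise ValueError("every position must appear in at least one subset")


def singleton_constraints(k: int) -> MarginalConstraintSet:
    return MarginalConstraintSet(k, tuple((i,) for i in range(k)))


def adjacent_pair_constraints(k: int) -> MarginalConstraintSet:
    """Default: all single positions plus all adjacent position pairs."""
    subs = [(i,) for i in range(k)] + [(i, i + 1) for i in range(k - 1)]
    return MarginalConstraintSet(k, tuple(subs))


def full_constraints(k: int) -> MarginalConstraintSet:
    return MarginalConstraintSet(k, (tuple(range(k)),))


def empirical_distribution(
    windows: Sequence[str], k: int, pseudocount: float
) -> np.ndarray:
    """Pseudocounted empirical joint over 4^k outcomes, shape (4,)*k.

    ``pseudocount`` is the *total* pseudo-observation mass, spread
    uniformly over the 4^k outcomes (so its weight relative to the data is
    independent of window width).
    """
    counts = np.full((4,) * k, float(pseudocount) / 4**k)
    for w in windows:
        if len(w) != k:
            raise ValueError(f"window {w!r} has width {len(w)}, expected {k}")
        counts[encode(w)] += 1.0
    return counts / counts.sum()


@dataclass
class MaxEntDistribution:
    """A dense maximum-entropy distribution over 4^k windows."""

    k: int
    probs: np.ndarray  # shape (4,)*k
    constraints: MarginalConstraintSet
    pseudocount: float
    max_marginal_dev: float
    n_iter: int
    converged: bool
    log_likelihood_path: list[float] = field(default_factory=list)

    def prob(self, window: str) -> float:
        if len(window) != self.k:
            raise ValueError(f"window width {len(window)} != model width {self.k}")
        return float(self.probs[encode(window)])

    def log2prob(self, window: str) -> float:
        return float(np.log2(self.prob(window)))

    def marginal(self, subset: tuple[int, ...]) -> np.ndarray:
        axes = tuple(i for i in range(self.k) if i not in subset)
        return self.probs.sum(axis=axes)


def _marginal(p: np.ndarray, subset: tuple[int, ...], k: int) -> np.ndarray:
    axes = tuple(i for i in range(k) if i not in subset)
    return p.sum(axis=axes) if axes else p


def _expand(m: np.ndarray, subset: tuple[int, ...], k: int) -> np.ndarray:
    shape = [1] * k
    for p in subset:
        shape[p] = 4
    return m.reshape(shape)


def train_maxent(
    windows: Sequence[str],
    constraints: MarginalConstraintSet | None = None,
    pseudocount: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> MaxEntDistribution:
    """Fit a dense maximum-entropy distribution by iterative proportional fitting.

    Starting from the uniform distribution, each sweep rescales the current
    fit so that its marginal over every constrained subset matches the
    pseudocounted empirical marginal; convergence is declared when the
    largest absolute marginal deviation falls below ``tol``. The training
    log-likelihood is non-decreasing across sweeps (recorded in
    ``log_likelihood_path``).
    """
    if not windows:
        raise ValueError("empty training set")
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"inconsistent window widths: {sorted(widths)}")
    k = widths.pop()
    if k > DENSE_WIDTH_LIMIT:
        raise ValueError(
            f"window width {k} too large for a dense fit; use train_factorized"
        )
    if constraints is None:
        constraints = adjacent_pair_constraints(k)
    if constraints.k != k:
        raise ValueError("constraint width does not match window width")

    emp = empirical_distribution(windows, k, pseudocount)
    targets = {s: _marginal(emp, s, k) for s in constraints.subsets}
    for s, t in targets.items():
        if np.any(t <= 0):
            raise ValueError(
                f"zero-probability constraint cell in subset {s}; "
                "use a positive pseudocount"
            )

    counts = np.zeros((4,) * k)
    for w in windows:
        counts[encode(w)] += 1.0

    q = np.full((4,) * k, 1.0 / 4**k)
    ll_path: list[float] = []
    n_iter = 0
    max_dev = np.inf
    for n_iter in range(1, max_iter + 1):
        for s in constraints.subsets:
            m = _marginal(q, s, k)
            q *= _expand(targets[s] / m, s, k)
        q /= q.sum()  # guard against numeric drift
        ll_path.append(float((counts * np.log(q)).sum()))
        max_dev = max(
            float(np.abs(_marginal(q, s, k) - targets[s]).max())
            for s in constraints.subsets
        )
        if max_dev <= tol:
            break
    return MaxEntDistribution(
        k=k,
        probs=q,
        constraints=constraints,
        pseudocount=pseudocount,
        max_marginal_dev=max_dev,
        n_iter=n_iter,
        converged=max_dev <= tol,
        log_likelihood_path=ll_path,
    )


# ---------------------------------------------------------------------------
# Factorized (long-window) model


@dataclass
class FactorizedMaxEnt:
    """Joint distribution over a long window as a chain of fragment conditionals.

    Fragments are position subsets fitted densely; fragment i > 0
    contributes P_i(new positions | overlap with previously covered
    positions), with the overlap marginal taken from the fragment's own
    distribution, so the joint sums to exactly 1 for any layout. Positions
    in ``fixed_positions`` (obligate dinucleotides) are excluded from the
    model; their bases are checked at scoring time.
    """

    k: int
    fragments: list[tuple[tuple[int, ...], MaxEntDistribution]]
    fixed_positions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        covered: set[int] = set()
        for pos, _ in self.fragments:
            covered.update(pos)
        modeled = set(range(self.k)) - set(self.fixed_positions)
        if covered != modeled:
            missing = sorted(modeled - covered)
            raise ValueError(f"fragment layout leaves positions uncovered: {missing}")

    @property
    def converged(self) -> bool:
        return all(d.converged for _, d in self.fragments)

    def log2prob(self, window: str) -> float:
        if len(window) != self.k:
            raise ValueError(f"window width {len(window)} != model width {self.k}")
        for pos, base in self.fixed_positions.items():
            if window[pos] != base:
                return float("-inf")
        total = 0.0
        covered: set[int] = set()
        for pos, dist in self.fragments:
            sub = "".join(window[p] for p in pos)
            total += dist.log2prob(sub)
            ov = tuple(i for i, p in enumerate(pos) if p in covered)
            if ov:
                ov_marg = _marginal(dist.probs, ov, len(pos))
                idx = tuple(_BASE_INDEX[sub[i]] for i in ov)
                total -= float(np.log2(ov_marg[idx]))
            covered.update(pos)
        return total

    def prob(self, window: str) -> float:
        return float(2.0 ** self.log2prob(window))


def consecutive_fragment_layout(
    positions: Sequence[int], width: int = 7, overlap: int = 2
) -> list[tuple[int, ...]]:
    """Cover ``positions`` (sorted) with consecutive windows of ``width``
    positions overlapping by ``overlap``."""
    positions = sorted(positions)
    n = len(positions)
    layout = []
    start = 0
    while True:
        end = min(start + width, n)
        layout.append(tuple(positions[start:end]))
        if end == n:
            break
        start = end - overlap
    return layout


def train_factorized(
    windows: Sequence[str],
    fragment_layout: Sequence[Sequence[int]],
    constraints_factory=adjacent_pair_constraints,
    fixed_positions: dict[int, str] | None = None,
    pseudocount: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> FactorizedMaxEnt:
    """Fit a factorized maximum-entropy model for long windows.

    Each fragment (a set of window positions) is fitted densely by
    ``train_maxent`` on the corresponding subwindows; the joint is the
    chain of fragment conditionals (see FactorizedMaxEnt).
    """
    if not windows:
        raise ValueError("empty training set")
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"inconsistent window widths: {sorted(widths)}")
    k = widths.pop()
    fixed_positions = dict(fixed_positions or {})
    fragments = []
    for pos in fragment_layout:
        pos = tuple(sorted(pos))
        subwindows = ["".join(w[p] for p in pos) for w in windows]
        dist = train_maxent(
            subwindows,
            constraints=constraints_factory(len(pos)),
            pseudocount=pseudocount,
            tol=tol,
            max_iter=max_iter,
        )
        fragments.append((pos, dist))
    return FactorizedMaxEnt(k=k, fragments=fragments, fixed_positions=fixed_positions)


ACCEPTOR_FIXED = {ACCEPTOR_INTRONIC - 2: "A", ACCEPTOR_INTRONIC - 1: "G"}


def acceptor_fragment_layout(width: int = 7, overlap: int = 2) -> list[tuple[int, ...]]:
    """Default acceptor layout: consecutive fragments over the 21 non-AG positions."""
    modeled = [p for p in range(ACCEPTOR_WIDTH) if p not in ACCEPTOR_FIXED]
    return consecutive_fragment_layout(modeled, width=width, overlap=overlap)


# ---------------------------------------------------------------------------
# Zero-order background (fallback)


@dataclass
class ZeroOrderModel:
    """Mononucleotide (zero-order) window distribution: P(w) = prod p(base)."""

    k: int
    base_probs: np.ndarray  # shape (4,)

    def log2prob(self, window: str) -> float:
        if len(window) != self.k:
            raise ValueError(f"window width {len(window)} != model width {self.k}")
        return float(sum(np.log2(self.base_probs[_BASE_INDEX[b]]) for b in window))

    def prob(self, window: str) -> float:
        return float(2.0 ** self.log2prob(window))

    @property
    def converged(self) -> bool:
        return True


def zero_order_model(sequences: Sequence[str], k: int, pseudocount: float = 1.0) -> ZeroOrderModel:
    counts = np.full(4, float(pseudocount))
    for seq in sequences:
        for b in seq:
            if b in _BASE_INDEX:
                counts[_BASE_INDEX[b]] += 1.0
    return ZeroOrderModel(k=k, base_probs=counts / counts.sum())


# ---------------------------------------------------------------------------
# Window collection


def collect_training_windows(
    introns: Sequence[IntronRecord], site_kind: str
) -> list[str]:
    """Signal windows from surveyed introns (duplicates retained).

    Windows containing N or overhanging the transcript are excluded. The
    32-nt minimum intron size guarantees the donor (6 intronic nt) and
    acceptor (20 intronic nt) windows never overlap within an intron.
    """
    if site_kind == "donor":
        out = [i.donor_window for i in introns if i.donor_window_ok]
    elif site_kind == "acceptor":
        out = [i.acceptor_window for i in introns if i.acceptor_window_ok]
    else:
        raise ValueError(f"unknown site kind {site_kind!r}")
    if not out:
        raise ValueError(f"no usable {site_kind} training windows")
    return out


def collect_background_windows(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    site_kind: str,
    rng: np.random.Generator,
    max_windows: int = 50_000,
) -> list[str]:
    """Decoy windows from surveyed pre-mRNAs.

    A decoy carries the obligate dinucleotide at the annotated-site offset
    (GT at intron positions +1/+2 for donors; AG at -2/-1 for acceptors)
    but is not itself an annotated splice site.
    """
    if site_kind not in ("donor", "acceptor"):
        raise ValueError(f"unknown site kind {site_kind!r}")
    out: list[str] = []
    for tx in transcripts:
        pre = premrna_sequence(tx, genome)
        donors, acceptors = annotated_site_positions(tx)
        if site_kind == "donor":
            annotated = set(donors)
            dinuc, offset, width = "GT", DONOR_EXONIC, DONOR_WIDTH
        else:
            annotated = set(acceptors)
            dinuc, offset, width = "AG", ACCEPTOR_INTRONIC - 2, ACCEPTOR_WIDTH
        # scan dinucleotide occurrences; window start places it at `offset`
        j = pre.find(dinuc)
        while j != -1:
            i = j - offset
            if 0 <= i <= len(pre) - width:
                site = j if site_kind == "donor" else j + 2
                if site not in annotated:
                    w = pre[i : i + width]
                    if "N" not in w:
                        out.append(w)
            j = pre.find(dinuc, j + 1)
    if not out:
        raise ValueError("no background windows found")
    if len(out) > max_windows:
        idx = rng.choice(len(out), size=max_windows, replace=False)
        out = [out[j] for j in sorted(idx)]
    return out


# ---------------------------------------------------------------------------
# Scoring


@dataclass
class SpliceSiteModel:
    """Paired signal/background distributions; scores in log2-odds bits."""

    site_kind: str
    signal: object  # MaxEntDistribution | FactorizedMaxEnt | ZeroOrderModel
    background: object

    def __post_init__(self):
        if self.signal.k != self.background.k:
            raise ValueError("signal and background must share window width")
        self.k = self.signal.k

    def score(self, window: str) -> float | None:
        """log2(P_signal / P_background); None when the window contains N."""
        if len(window) != self.k:
            raise ValueError(f"window width {len(window)} != model width {self.k}")
        if "N" in window:
            return None
        return self.signal.log2prob(window) - self.background.log2prob(window)

    def score_many(self, windows: Sequence[str | None]) -> np.ndarray:
        out = np.full(len(windows), np.nan)
        for j, w in enumerate(windows):
            if w is None or "N" in w:
                continue
            out[j] = self.score(w)
        return out


def score_site(model: SpliceSiteModel, window: str) -> float | None:
    return model.score(window)


def train_donor_model(
    signal_windows: Sequence[str],
    background_windows: Sequence[str],
    pseudocount: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> SpliceSiteModel:
    constraints = adjacent_pair_constraints(DONOR_WIDTH)
    return SpliceSiteModel(
        site_kind="donor",
        signal=train_maxent(signal_windows, constraints, pseudocount, tol, max_iter),
        background=train_maxent(
            background_windows, constraints, pseudocount, tol, max_iter
        ),
    )


def train_acceptor_model(
    signal_windows: Sequence[str],
    background_windows: Sequence[str],
    pseudocount: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> SpliceSiteModel:
    layout = acceptor_fragment_layout()
    return SpliceSiteModel(
        site_kind="acceptor",
        signal=train_factorized(
            signal_windows,
            layout,
            fixed_positions=ACCEPTOR_FIXED,
            pseudocount=pseudocount,
            tol=tol,
            max_iter=max_iter,
        ),
        background=train_factorized(
            background_windows,
            layout,
            fixed_positions=ACCEPTOR_FIXED,
            pseudocount=pseudocount,
            tol=tol,
            max_iter=max_iter,
        ),
    )


# ---------------------------------------------------------------------------
# Strength quartiles


@dataclass(frozen=True)
class StrengthQuartiles:
    """Cut points splitting scores into weak / moderately weak /
    moderately strong / strong; boundary values go to the lower class."""

    cuts: tuple[float, float, float]
    degenerate: bool = False

    def label(self, score: float) -> str:
        idx = int(np.searchsorted(np.asarray(self.cuts), score, side="left"))
        return QUARTILE_LABELS[idx]


def assign_quartiles(scores: Sequence[float]) -> tuple[StrengthQuartiles, list[str]]:
    """Empirical 25/50/75-percentile cuts and per-score class labels."""
    arr = np.asarray([s for s in scores if s is not None and np.isfinite(s)], dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 finite scores for quartiles")
    cuts = tuple(float(c) for c in np.percentile(arr, [25, 50, 75]))
    degenerate = not (cuts[0] < cuts[1] < cuts[2])
    q = StrengthQuartiles(cuts=cuts, degenerate=degenerate)
    labels = [
        q.label(s) if s is not None and np.isfinite(s) else "undefined" for s in scores
    ]
    return q, labels


# ---------------------------------------------------------------------------
# Serialization (versioned flat text, deterministic)

_FORMAT_VERSION = 1


def _write_dense(fh, dist: MaxEntDistribution, name: str) -> None:
    fh.write(f"dense {name}\n")
    fh.write(f"k {dist.k}\n")
    fh.write(f"pseudocount {dist.pseudocount!r}\n")
    fh.write(
        "constraints " + ";".join(",".join(map(str, s)) for s in dist.constraints.subsets) + "\n"
    )
    fh.write(f"converged {int(dist.converged)}\n")
    fh.write("probs\n")
    for v in dist.probs.ravel():
        fh.write(f"{float(v)!r}\n")


def _read_dense(lines, i):
    name = lines[i].split(" ", 1)[1]
    k = int(lines[i + 1].split()[1])
    pseudocount = float(lines[i + 2].split()[1])
    subsets = tuple(
        tuple(int(x) for x in part.split(","))
        for part in lines[i + 3].split(" ", 1)[1].split(";")
    )
    converged = bool(int(lines[i + 4].split()[1]))
    assert lines[i + 5] == "probs"
    n = 4**k
    vals = np.array([float(x) for x in lines[i + 6 : i + 6 + n]])
    dist = MaxEntDistribution(
        k=k,
        probs=vals.reshape((4,) * k),
        constraints=MarginalConstraintSet(k, subsets),
        pseudocount=pseudocount,
        max_marginal_dev=float("nan"),
        n_iter=0,
        converged=converged,
    )
    return dist, name, i + 6 + n


def save_model(model: SpliceSiteModel, path: str | Path) -> None:
    """Serialize as versioned flat text; re-serialization is byte-identical."""
    with open(path, "w") as fh:
        fh.write(f"# genearch splice-site model v{_FORMAT_VERSION}\n")
        fh.write(f"site_kind {model.site_kind}\n")
        for name, dist in (("signal", model.signal), ("background", model.background)):
            if isinstance(dist, MaxEntDistribution):
                _write_dense(fh, dist, name)
            elif isinstance(dist, FactorizedMaxEnt):
                fh.write(f"factorized {name}\n")
                fh.write(f"k {dist.k}\n")
                fixed = ";".join(f"{p},{b}" for p, b in sorted(dist.fixed_positions.items()))
                fh.write(f"fixed {fixed}\n")
                fh.write(f"n_fragments {len(dist.fragments)}\n")
                for pos, frag in dist.fragments:
                    fh.write("positions " + ",".join(map(str, pos)) + "\n")
                    _write_dense(fh, frag, "fragment")
            else:
                raise TypeError(f"cannot serialize {type(dist).__name__}")


def load_model(path: str | Path) -> SpliceSiteModel:
    lines = Path(path).read_text().splitlines()
    if not lines[0].startswith("# genearch splice-site model v"):
        raise ValueError("not a genearch splice-site model file")
    site_kind = lines[1].split()[1]
    i = 2
    parts = {}
    while i < len(lines):
        kind, name = lines[i].split(" ", 1)
        if kind == "dense":
            dist, name, i = _read_dense(lines, i)
            parts[name] = dist
        elif kind == "factorized":
            k = int(lines[i + 1].split()[1])
            fixed_field = lines[i + 2].split(" ", 1)
            fixed = {}
            if len(fixed_field) > 1 and fixed_field[1]:
                for part in fixed_field[1].split(";"):
                    p, b = part.split(",")
                    fixed[int(p)] = b
            n_frag = int(lines[i + 3].split()[1])
            i += 4
            frags = []
            for _ in range(n_frag):
                pos = tuple(int(x) for x in lines[i].split(" ", 1)[1].split(","))
                frag, _, i2 = _read_dense(lines, i + 1)
                frags.append((pos, frag))
                i = i2
            parts[name] = FactorizedMaxEnt(k=k, fragments=frags, fixed_positions=fixed)
        else:
            raise ValueError(f"unexpected line in model file: {lines[i]!r}")
    return SpliceSiteModel(site_kind=site_kind, signal=parts["signal"], background=parts["background"])
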