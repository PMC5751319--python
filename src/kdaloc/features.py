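"""PSSM profiles and the PsePSSM / PSSM-S protein feature encodings.

A position-specific scoring matrix (PSSM) from PSI-BLAST is an L x 20
table of evolutionary log-odds scores, one row per sequence position and
one column per amino-acid type.  Two fixed-length encodings of a variable
length profile are provided:

PsePSSM (1000 features by default)
    20 column means plus, for each lag xi = 1..49, 20 lagged
    mean-squared-difference correlation factors:

        Mbar_j  = (1/L) sum_i M[i, j]
        G_j(xi) = (1/(L - xi)) sum_i (M[i, j] - M[i + xi, j])^2

PSSM-S (220 features)
    Four blocks: AAO (20, amino-acid occurrence of the profile's consensus
    sequence), PSSM-AAO (20, column means), PSSM-SD (80, segmented
    distribution: per column, normalized positions where the running sum of
    absolute scores first reaches 25% and 50% of the column total, walked
    from each terminus) and PSSM-SAC (100, mean-centered auto covariance at
    lags 1..5 per column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CANONICAL_AA_ORDER",
    "PSSMProfile",
    "PsePSSMVector",
    "PSSMSVector",
    "parse_pssm",
    "write_pssm",
    "pse_pssm",
    "pssm_s",
    "write_feature_matrix",
]

CANONICAL_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class PSSMProfile:
    """One protein's L x 20 substitution-score table.

    Attributes
    ----------
    scores : ndarray of shape (L, 20)
        Score of mutating position ``i`` to amino-acid type ``j``.
    sequence : str or None
        The residue letters, when known (length L).
    aa_order : str
        The 20 amino-acid letters in column order.
    """

    scores: np.ndarray
    sequence: str | None = None
    aa_order: str = CANONICAL_AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got shape {self.scores.shape}")
        if self.scores.shape[0] < 1:
            raise ValueError("profile must have at least one position")
        if len(self.aa_order) != 20 or len(set(self.aa_order)) != 20:
            raise ValueError("aa_order must be 20 distinct letters")
        if self.sequence is not None and len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != profile length {self.scores.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        """Consensus sequence: per-row argmax column (ties -> lowest column index)."""
        return "".join(self.aa_order[j] for j in np.argmax(self.scores, axis=1))


@dataclass
class PsePSSMVector:
    """PsePSSM encoding: column means plus lagged correlation blocks."""

    mean_block: np.ndarray  # 20 values Mbar_j
    correlation_blocks: np.ndarray  # xi_max x 20 values G_j(xi)
    xi_max: int

    def to_array(self) -> np.ndarray:
        """Concatenate as [Mbar_1..Mbar_20, G(1), G(2), ..., G(xi_max)]."""
        return np.concatenate([self.mean_block, self.correlation_blocks.ravel()])

    def __len__(self) -> int:
        return 20 * (1 + self.xi_max)


@dataclass
class PSSMSVector:
    """PSSM-S encoding: AAO + PSSM-AAO + PSSM-SD + PSSM-SAC = 220 features."""

    aao: np.ndarray  # 20
    pssm_aao: np.ndarray  # 20
    pssm_sd: np.ndarray  # 80
    pssm_sac: np.ndarray  # 100

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.aao, self.pssm_aao, self.pssm_sd, self.pssm_sac])

    def __len__(self) -> int:
        return 220


def _is_aa_header(tokens: list[str]) -> bool:
    return len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens)


def parse_pssm(text: str) -> PSSMProfile:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content into a :class:`PSSMProfile`.

    Only the first 20-score block (log-odds) is used; the optional 20
    percentage columns and the two trailing per-position floats are
    ignored.  Column order follows the letters printed in the file's
    header line; without such a header the canonical order
    ``ARNDCQEGHILKMFPSTWYV`` is assumed.

    Raises
    ------
    ValueError
        On a malformed score row (naming the 1-based line number) or when
        the file contains no score rows.
    """
    aa_order = CANONICAL_AA_ORDER
    rows: list[list[float]] = []
    letters: list[str] = []
    in_body = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            if in_body:
                break  # blank line after the body starts the footer
            continue
        if not in_body and _is_aa_header(tokens):
            aa_order = "".join(tokens[:20])
            continue
        starts_numeric = tokens[0].lstrip("-").isdigit()
        if not starts_numeric:
            if in_body:
                break  # footer (Lambda/K statistics)
            continue  # header commentary
        in_body = True
        # position index, residue letter, then the score columns
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise ValueError(f"line {lineno}: expected 'pos residue scores...', got: {line!r}")
        body = tokens[2:]
        if len(body) not in (20, 40, 42):
            raise ValueError(
                f"line {lineno}: expected 20 scores (plus optional 20 percentages "
                f"and 2 weights), found {len(body)} numeric fields"
            )
        try:
            rows.append([float(v) for v in body[:20]])
        except ValueError as err:
            raise ValueError(f"line {lineno}: non-numeric score field: {err}") from None
        letters.append(tokens[1].upper())
    if not rows:
        raise ValueError("no PSSM score rows found (empty body)")
    return PSSMProfile(np.asarray(rows), sequence="".join(letters), aa_order=aa_order)


def write_pssm(profile: PSSMProfile, identifier: str = "query") -> str:
    """Render a profile in the PSI-BLAST ASCII dialect (round-trips through
    :func:`parse_pssm`)."""
    seq = profile.sequence or profile.consensus()
    lines = [
        "",
        f"Last position-specific scoring matrix computed for {identifier}",
        "            " + "   ".join(profile.aa_order),
    ]
    for i, row in enumerate(profile.scores, start=1):
        fields = " ".join(f"{v:4g}" for v in row)
        lines.append(f"{i:5d} {seq[i - 1]}  {fields}")
    lines.append("")
    lines.append("                      K         Lambda")
    return "\n".join(lines) + "\n"


def _prepare_scores(profile: PSSMProfile, normalize: str) -> np.ndarray:
    if normalize == "none":
        return profile.scores
    if normalize == "logistic":
        return 1.0 / (1.0 + np.exp(-profile.scores))
    raise ValueError(f"unknown normalization {normalize!r} (use 'none' or 'logistic')")


def pse_pssm(profile: PSSMProfile, xi_max: int = 49, normalize: str = "none") -> PsePSSMVector:
    """PsePSSM encoding of a profile: 20 column means + 20 * xi_max lag factors.

    Parameters
    ----------
    profile : PSSMProfile
    xi_max : int
        Largest lag; must be < L.  The default 49 yields the standard
        1000-dimensional vector.
    normalize : {'none', 'logistic'}
        Optional elementwise squashing of the raw scores before encoding.

    Raises
    ------
    ValueError
        When ``xi_max >= L``: use a shorter lag or a longer sequence.
    """
    if xi_max < 1:
        raise ValueError(f"xi_max must be >= 1, got {xi_max}")
    M = _prepare_scores(profile, normalize)
    L = profile.length
    if xi_max >= L:
        raise ValueError(
            f"xi_max={xi_max} must be smaller than the profile length L={L}; "
            f"use a shorter lag or a longer sequence"
        )
    mean_block = M.mean(axis=0)
    corr = np.empty((xi_max, 20))
    for xi in range(1, xi_max + 1):
        diff = M[:-xi] - M[xi:]
        corr[xi - 1] = np.mean(diff**2, axis=0)
    return PsePSSMVector(mean_block=mean_block, correlation_blocks=corr, xi_max=xi_max)


def _segmented_distribution(col: np.ndarray, fractions=(0.25, 0.50)) -> list[float]:
    """Normalized 1-based positions where the running |score| sum first reaches
    each fraction of the column total, from the N- then the C-terminus."""
    L = col.size
    mags = np.abs(col)
    total = mags.sum()
    out: list[float] = []
    for series in (mags, mags[::-1]):
        cum = np.cumsum(series)
        for frac in fractions:
            if total == 0:
                out.append(0.0)
            else:
                pos = int(np.searchsorted(cum, frac * total)) + 1
                out.append(pos / L)
    return out


def pssm_s(
    profile: PSSMProfile,
    sac_lags: int = 5,
    sd_fractions=(0.25, 0.50),
    normalize: str = "none",
) -> PSSMSVector:
    """PSSM-S encoding: AAO (20) + PSSM-AAO (20) + PSSM-SD (80) + PSSM-SAC (100).

    Requires ``L > sac_lags`` (the largest auto-covariance lag must leave at
    least one score pair); L >= 20 is recommended so segments are informative.
    """
    M = _prepare_scores(profile, normalize)
    L = profile.length
    if L <= sac_lags:
        raise ValueError(
            f"profile length L={L} too short for auto-covariance lags 1..{sac_lags}"
        )

    # AAO: occurrence frequencies of the consensus sequence, canonical order
    consensus = profile.consensus()
    aao = np.array([consensus.count(a) for a in profile.aa_order], dtype=float) / L

    pssm_aao = M.sum(axis=0) / L

    sd = np.array([_segmented_distribution(M[:, j], sd_fractions) for j in range(20)])

    means = M.mean(axis=0)
    centered = M - means
    sac = np.empty((20, sac_lags))
    for g in range(1, sac_lags + 1):
        sac[:, g - 1] = np.sum(centered[:-g] * centered[g:], axis=0) / (L - g)

    return PSSMSVector(
        aao=aao,
        pssm_aao=pssm_aao,
        pssm_sd=sd.ravel(),
        pssm_sac=sac.ravel(),
    )


def write_feature_matrix(path, ids, features, labels=None, feature_names=None) -> None:
    """Write a feature matrix as TSV: header, then ``id [label] f1 f2 ...`` per row."""
    import pandas as pd

    features = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(features.shape[1])]
    df = pd.DataFrame(features, columns=feature_names)
    if labels is not None:
        df.insert(0, "label", list(labels))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)
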