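"""Audio front-end: WAV <-> 12-dim MFCC frame sequences.

Framing follows the speech-standard 25 ms analysis window with a stride
(hop) of 10 ms (overlapping) or 25 ms (non-overlapping): the frame count of
a signal of duration ``D`` is ``floor((D - frame) / stride) + 1``.  Each
frame yields 12 mel-frequency cepstral coefficients (the 0th, energy-like
coefficient is excluded; 26-filter mel bank, pre-emphasis 0.97, Hamming
window — conventional defaults, all configurable).

Raw cepstra are affinely mapped to a non-negative dynamic range (default
``[0, 1200]``); the mapping is stored in the sequence metadata so that
inversion can undo it.  ``mfcc_to_wav`` performs best-effort inversion
(inverse DCT -> mel pseudo-inverse -> Griffin-Lim phase recovery); the
contract is cepstral round-trip fidelity, not perceptual quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.fft import dct, idct
from scipy.io import wavfile
from scipy.signal import istft, stft

__all__ = [
    "MFCCSequence",
    "n_frames",
    "wav_to_mfcc",
    "mfcc_to_wav",
    "save_sequence",
    "load_sequence",
    "export_text",
]

MFCC_RANGE = (0.0, 1200.0)


@dataclass
class MFCCSequence:
    """Ordered 12-dim real frames plus framing/scaling metadata."""

    frames: np.ndarray
    frame_ms: int = 25
    stride_ms: int = 10
    sample_rate: int = 16000
    labels: np.ndarray | None = None
    scale_lo: float = MFCC_RANGE[0]
    scale_hi: float = MFCC_RANGE[1]
    affine_min: float = 0.0   # raw cepstral value mapped to scale_lo
    affine_scale: float = 1.0  # scaled units per raw unit

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty T x M matrix")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.stride_ms > self.frame_ms:
            raise ValueError("stride must not exceed the frame length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.frames.shape[0]:
                raise ValueError("one label per frame required")

    @property
    def t(self) -> int:
        return self.frames.shape[0]

    @property
    def m(self) -> int:
        return self.frames.shape[1]

    def raw(self) -> np.ndarray:
        """Undo the affine range mapping back to raw cepstra."""
        return (self.frames - self.scale_lo) / self.affine_scale + self.affine_min


def n_frames(duration_s: float, frame_ms: int = 25, stride_ms: int = 10) -> int:
    """``floor((duration - frame) / stride) + 1`` in milliseconds."""
    return int((duration_s * 1000.0 - frame_ms) // stride_ms) + 1


# ---------------------------------------------------------------------------
# mel machinery
# ---------------------------------------------------------------------------


def _hz_to_mel(hz):
    return 2595.0 * np.log10(1.0 + np.asarray(hz, dtype=float) / 700.0)


def _mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, nfft: int, sr: int) -> np.ndarray:
    """Triangular mel filters over the one-sided FFT bins."""
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0), _hz_to_mel(sr / 2), n_mels + 2))
    bins = np.floor((nfft + 1) * edges / sr).astype(int)
    fb = np.zeros((n_mels, nfft // 2 + 1))
    for j in range(n_mels):
        l, c, r = bins[j], bins[j + 1], bins[j + 2]
        c = max(c, l + 1)
        r = max(r, c + 1)
        fb[j, l:c] = (np.arange(l, c) - l) / (c - l)
        fb[j, c:r] = (r - np.arange(c, r)) / (r - c)
    return fb


def _frame_params(frame_ms: int, stride_ms: int, sr: int) -> tuple[int, int, int]:
    flen = int(round(sr * frame_ms / 1000.0))
    hop = int(round(sr * stride_ms / 1000.0))
    nfft = 1 << (flen - 1).bit_length()
    return flen, hop, nfft


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def signal_to_mfcc(
    signal: np.ndarray,
    sample_rate: int,
    stride_ms: int = 10,
    frame_ms: int = 25,
    n_coeff: int = 12,
    n_mels: int = 26,
    preemphasis: float = 0.97,
    scale_lo: float = MFCC_RANGE[0],
    scale_hi: float = MFCC_RANGE[1],
) -> MFCCSequence:
    """MFCC extraction from a mono float signal (deterministic)."""
    signal = np.asarray(signal, dtype=float)
    flen, hop, nfft = _frame_params(frame_ms, stride_ms, sample_rate)
    if signal.size < flen:
        raise ValueError("signal shorter than one analysis frame")
    emph = np.concatenate([signal[:1], signal[1:] - preemphasis * signal[:-1]])
    t = (signal.size - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(t)[:, None]
    framed = emph[idx] * np.hamming(flen)
    power = np.abs(np.fft.rfft(framed, nfft, axis=1)) ** 2 / nfft
    fb = _mel_filterbank(n_mels, nfft, sample_rate)
    mel = np.maximum(power @ fb.T, 1e-12)
    cep = dct(np.log(mel), type=2, norm="ortho", axis=1)
    raw = cep[:, 1 : n_coeff + 1]
    rmin, rmax = float(raw.min()), float(raw.max())
    scale = (scale_hi - scale_lo) / (rmax - rmin) if rmax > rmin else 1.0
    frames = (raw - rmin) * scale + scale_lo
    return MFCCSequence(
        frames=frames,
        frame_ms=frame_ms,
        stride_ms=stride_ms,
        sample_rate=sample_rate,
        scale_lo=scale_lo,
        scale_hi=scale_hi,
        affine_min=rmin,
        affine_scale=scale,
    )


def wav_to_mfcc(path: str | Path, stride_ms: int = 10, **kwargs) -> MFCCSequence:
    """Read a PCM WAV file (mono, or stereo downmixed) and extract MFCCs."""
    path = Path(path)
    try:
        sr, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        if data.shape[1] > 2:
            raise ValueError(f"{path}: more than two channels cannot be normalized")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return signal_to_mfcc(data.astype(float), sr, stride_ms=stride_ms, **kwargs)


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def mfcc_to_signal(
    seq: MFCCSequence,
    n_mels: int = 26,
    griffin_lim_iters: int = 32,
) -> np.ndarray:
    """Best-effort waveform from an MFCC sequence.

    The missing 0th cepstral coefficient is taken as zero (per-frame gain is
    unidentifiable from 12 coefficients); the mel spectrum is recovered with
    a regularized pseudo-inverse of the filterbank and the phase with
    Griffin-Lim iterations.  Output length is ``(T-1)*stride + frame``.
    """
    sr = seq.sample_rate
    flen, hop, nfft = _frame_params(seq.frame_ms, seq.stride_ms, sr)
    raw = seq.raw()
    cep = np.zeros((seq.t, n_mels))
    cep[:, 1 : seq.m + 1] = raw
    logmel = np.clip(idct(cep, type=2, norm="ortho", axis=1), -60.0, 60.0)
    mel = np.exp(logmel)
    fb = _mel_filterbank(n_mels, nfft, sr)
    # ridge-regularized least squares back to the power spectrum
    gram = fb @ fb.T + 1e-8 * np.eye(n_mels)
    power = np.maximum(mel @ np.linalg.solve(gram, fb), 1e-12)
    mag = np.sqrt(power).T  # (freq, T)

    window = np.hamming(flen)
    noverlap = flen - hop
    phase = np.exp(2j * np.pi * np.random.default_rng(0).random(mag.shape))
    spec = mag * phase
    x = None
    for _ in range(griffin_lim_iters):
        _, x = istft(
            spec, fs=sr, window=window, nperseg=flen, noverlap=noverlap,
            nfft=nfft, input_onesided=True, boundary=True,
        )
        _, _, est = stft(
            x, fs=sr, window=window, nperseg=flen, noverlap=noverlap,
            nfft=nfft, boundary="zeros", padded=True,
        )
        est = est[:, : mag.shape[1]]
        if est.shape[1] < mag.shape[1]:
            est = np.pad(est, ((0, 0), (0, mag.shape[1] - est.shape[1])))
        spec = mag * np.exp(1j * np.angle(est))
    target_len = (seq.t - 1) * hop + flen
    x = np.asarray(x)[:target_len]
    if x.size < target_len:
        x = np.pad(x, (0, target_len - x.size))
    peak = np.max(np.abs(x))
    return x / peak * 0.9 if peak > 0 else x


def mfcc_to_wav(seq: MFCCSequence, path: str | Path, **kwargs) -> Path:
    """Write the best-effort inversion of ``seq`` as 16-bit PCM mono."""
    x = mfcc_to_signal(seq, **kwargs)
    path = Path(path)
    wavfile.write(path, seq.sample_rate, (x * 32767).astype(np.int16))
    return path


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def save_sequence(seq: MFCCSequence, path: str | Path) -> None:
    """Bit-exact round-trippable binary container."""
    payload = {
        "frames": seq.frames,
        "meta": np.array(
            [seq.frame_ms, seq.stride_ms, seq.sample_rate], dtype=np.int64
        ),
        "scaling": np.array(
            [seq.scale_lo, seq.scale_hi, seq.affine_min, seq.affine_scale]
        ),
    }
    if seq.labels is not None:
        payload["labels"] = seq.labels
    np.savez(Path(path), **payload)


def load_sequence(path: str | Path) -> MFCCSequence:
    with np.load(Path(path)) as d:
        frame_ms, stride_ms, sr = (int(v) for v in d["meta"])
        lo, hi, amin, ascale = (float(v) for v in d["scaling"])
        return MFCCSequence(
            frames=d["frames"],
            frame_ms=frame_ms,
            stride_ms=stride_ms,
            sample_rate=sr,
            labels=d["labels"] if "labels" in d else None,
            scale_lo=lo,
            scale_hi=hi,
            affine_min=amin,
            affine_scale=ascale,
        )


def export_text(seq: MFCCSequence, path: str | Path) -> None:
    """Delimited-text export for inspection: one row per frame."""
    import pandas as pd

    df = pd.DataFrame(seq.frames, columns=[f"c{i+1}" for i in range(seq.m)])
    if seq.labels is not None:
        df.insert(0, "label", seq.labels)
    df.to_csv(Path(path), sep="\t", index=False)
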