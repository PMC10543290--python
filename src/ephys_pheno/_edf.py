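"""Minimal EDF (European Data Format) codec for continuous biosignals.

EDF stores a fixed 256-byte ASCII header, 256 ASCII bytes per signal, and
then data records of little-endian int16 samples, one block per signal per
record.  Signals may have different sampling rates (different sample counts
per record).  Amplitudes are affine-coded between a physical range
(phys_min..phys_max) and a digital range (dig_min..dig_max), so a round
trip is exact up to one quantization step (phys range / 65535).

Only the subset needed for EEG/EMG/activity telemetry is implemented:
uniform one-second data records, int16 samples, no annotations.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfSignal:
    label: str
    physical_dim: str
    sampling_rate_hz: float
    data: np.ndarray  # physical units
    transducer: str = ""
    prefilter: str = ""


@dataclass
class EdfFile:
    signals: list[EdfSignal]
    record_duration_s: float = 1.0
    n_records: int = 0
    patient_id: str = "X"
    recording_id: str = "X"
    start_date: str = "01.01.00"
    start_time: str = "00.00.00"
    meta: dict = field(default_factory=dict)


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _fmt8(x: float) -> str:
    """Render a float in at most 8 ASCII characters (EDF numeric field width)."""
    for digits in range(8, 1, -1):
        s = f"{x:.{digits}g}"
        if len(s) <= 8:
            return s
    raise FormatError(f"cannot encode {x} in an 8-character EDF field")


def _physical_range(data: np.ndarray) -> tuple[float, float]:
    """Symmetric physical range covering the data, exactly as stored on disk.

    The range is round-tripped through its 8-character ASCII rendering so the
    scale used for encoding matches what any reader will parse back.
    """
    amp = float(np.max(np.abs(data))) if len(data) else 0.0
    amp = amp * 1.0001 if amp > 0 else 1.0
    amp = abs(float(_fmt8(amp)))
    if amp == 0.0:
        amp = 1.0
    return -amp, amp


def write_edf_file(path, edf: EdfFile) -> None:
    record_dur = edf.record_duration_s
    n_sig = len(edf.signals)
    samples_per_record = []
    for sig in edf.signals:
        spr = sig.sampling_rate_hz * record_dur
        if abs(spr - round(spr)) > 1e-9:
            raise FormatError(
                f"signal {sig.label!r}: sampling rate {sig.sampling_rate_hz} Hz "
                f"does not give an integer sample count per {record_dur} s record"
            )
        samples_per_record.append(int(round(spr)))

    n_records_each = [
        len(sig.data) / spr for sig, spr in zip(edf.signals, samples_per_record)
    ]
    n_records = n_records_each[0]
    if any(abs(n - n_records) > 1e-9 for n in n_records_each):
        raise FormatError("signals span different numbers of data records")
    if abs(n_records - round(n_records)) > 1e-9:
        raise FormatError(
            f"signal length is not a whole number of {record_dur} s records"
        )
    n_records = int(round(n_records))

    header_bytes = 256 * (1 + n_sig)
    phys_mins, phys_maxs = [], []
    for sig in edf.signals:
        pm, px = _physical_range(sig.data)
        phys_mins.append(pm)
        phys_maxs.append(px)

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(edf.patient_id, 80))
        fh.write(_pad(edf.recording_id, 80))
        fh.write(_pad(edf.start_date, 8))
        fh.write(_pad(edf.start_time, 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad(f"{record_dur:g}", 8))
        fh.write(_pad(str(n_sig), 4))
        for sig in edf.signals:
            fh.write(_pad(sig.label, 16))
        for sig in edf.signals:
            fh.write(_pad(sig.transducer, 80))
        for sig in edf.signals:
            fh.write(_pad(sig.physical_dim, 8))
        for pm in phys_mins:
            fh.write(_pad(_fmt8(pm), 8))
        for pm in phys_maxs:
            fh.write(_pad(_fmt8(pm), 8))
        for _ in edf.signals:
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in edf.signals:
            fh.write(_pad(str(_DIG_MAX), 8))
        for sig in edf.signals:
            fh.write(_pad(sig.prefilter, 80))
        for spr in samples_per_record:
            fh.write(_pad(str(spr), 8))
        for _ in edf.signals:
            fh.write(_pad("", 32))

        digital = []
        for sig, pm, px in zip(edf.signals, phys_mins, phys_maxs):
            scale = (px - pm) / (_DIG_MAX - _DIG_MIN)
            dig = np.round((sig.data - pm) / scale + _DIG_MIN)
            digital.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))

        for rec in range(n_records):
            for dig, spr in zip(digital, samples_per_record):
                fh.write(dig[rec * spr : (rec + 1) * spr].tobytes())


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_edf_file(path) -> EdfFile:
    with open(path, "rb") as fh:
        version = _read_field(fh, 8)
        if version != "0":
            raise FormatError(f"not an EDF file (version field {version!r})")
        patient_id = _read_field(fh, 80)
        recording_id = _read_field(fh, 80)
        start_date = _read_field(fh, 8)
        start_time = _read_field(fh, 8)
        _read_field(fh, 8)  # header byte count
        _read_field(fh, 44)  # reserved
        try:
            n_records = int(_read_field(fh, 8))
            record_dur = float(_read_field(fh, 8))
            n_sig = int(_read_field(fh, 4))
        except ValueError as exc:
            raise FormatError(f"malformed EDF header: {exc}") from exc

        labels = [_read_field(fh, 16) for _ in range(n_sig)]
        transducers = [_read_field(fh, 80) for _ in range(n_sig)]
        dims = [_read_field(fh, 8) for _ in range(n_sig)]
        phys_mins = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        phys_maxs = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        dig_mins = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        dig_maxs = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        prefilters = [_read_field(fh, 80) for _ in range(n_sig)]
        samples_per_record = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        for _ in range(n_sig):
            _read_field(fh, 32)

        raw = [np.empty(n_records * spr) for spr in samples_per_record]
        for rec in range(n_records):
            for i, spr in enumerate(samples_per_record):
                block = np.frombuffer(fh.read(2 * spr), dtype="<i2")
                if len(block) < spr:
                    raise FormatError("truncated EDF data record")
                raw[i][rec * spr : (rec + 1) * spr] = block

    signals = []
    for i in range(n_sig):
        scale = (phys_maxs[i] - phys_mins[i]) / (dig_maxs[i] - dig_mins[i])
        phys = (raw[i] - dig_mins[i]) * scale + phys_mins[i]
        signals.append(
            EdfSignal(
                label=labels[i],
                physical_dim=dims[i],
                sampling_rate_hz=samples_per_record[i] / record_dur,
                data=phys,
                transducer=transducers[i],
                prefilter=prefilters[i],
            )
        )
    return EdfFile(
        signals=signals,
        record_duration_s=record_dur,
        n_records=n_records,
        patient_id=patient_id,
        recording_id=recording_id,
        start_date=start_date,
        start_time=start_time,
    )


def quantization_step(data: np.ndarray) -> float:
    """Physical size of one digital step for the range the writer would pick."""
    pm, px = _physical_range(data)
    return (px - pm) / (_DIG_MAX - _DIG_MIN)
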