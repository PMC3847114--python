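"""Watched-folder ingestion of a real-time volume stream.

The scanner side of a real-time session exports one reconstructed 3D volume
per repetition into a shared folder; the analysis side must pick each file
up as soon as it is complete and deliver a strictly ordered stream. Files
are matched by an index-encoding filename pattern (``vol_0007.nii`` by
default) and sorted by the encoded index, never by mtime or listing order.

A file is considered complete when its size is non-zero and unchanged
across two polls at least ``stable_ms`` apart — scanners are assumed to
write sequentially, so a stable size means the writer has moved on.
"""

from __future__ import annotations

import re
import time
from pathlib import Path
from typing import Iterator

from .volume import Volume, read_volume

__all__ = ["watch_folder", "StreamStallError", "DEFAULT_PATTERN"]

DEFAULT_PATTERN = r"vol_(\d+)\.nii(\.gz)?$"


class StreamStallError(RuntimeError):
    """No new volume appeared before the timeout."""

    def __init__(self, last_index: int, timeout: float):
        self.last_index = last_index
        super().__init__(
            f"stream stalled: no new volume within {timeout:.1f} s "
            f"(last index seen: {last_index})"
        )


def _scan(folder: Path, pattern: re.Pattern) -> dict[int, Path]:
    found: dict[int, Path] = {}
    for p in folder.iterdir():
        m = pattern.search(p.name)
        if m:
            found[int(m.group(1))] = p
    return found


def _wait_stable(path: Path, stable_ms: float, timeout: float) -> None:
    """Block until the file size is non-zero and unchanged across two polls."""
    deadline = time.monotonic() + timeout
    prev = -1
    while time.monotonic() < deadline:
        try:
            size = path.stat().st_size
        except FileNotFoundError:
            size = -1
        if size > 0 and size == prev:
            return
        prev = size
        time.sleep(stable_ms / 1000.0)
    raise StreamStallError(-1, timeout)


def watch_folder(
    path: str | Path,
    n_expected: int,
    timeout: float = 30.0,
    pattern: str = DEFAULT_PATTERN,
    poll_ms: float = 20.0,
    stable_ms: float = 50.0,
) -> Iterator[Volume]:
    """Yield exactly ``n_expected`` volumes from ``path`` in index order.

    Indices are read from the filename (first capture group of ``pattern``)
    and must cover 0..n_expected-1 with no gaps; a gap that persists past
    ``timeout`` raises :class:`StreamStallError` naming the last delivered
    index. Corrupt or unreadable files raise immediately.
    """
    folder = Path(path)
    if not folder.is_dir():
        raise FileNotFoundError(f"watched folder does not exist: {folder}")
    rx = re.compile(pattern)

    next_index = 0
    last_progress = time.monotonic()
    while next_index < n_expected:
        found = _scan(folder, rx)
        if next_index in found:
            fpath = found[next_index]
            _wait_stable(fpath, stable_ms, timeout)
            try:
                vol = read_volume(fpath, index=next_index)
            except Exception as exc:
                raise RuntimeError(
                    f"failed to parse streamed volume {fpath.name}: {exc}"
                ) from exc
            yield vol
            next_index += 1
            last_progress = time.monotonic()
            continue
        if time.monotonic() - last_progress > timeout:
            raise StreamStallError(next_index - 1, timeout)
        time.sleep(poll_ms / 1000.0)
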