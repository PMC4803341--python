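"""Run log: timestamped INFO/WARN/ERROR lines, mirrored to a file and kept in memory."""
from __future__ import annotations

import datetime as _dt
from pathlib import Path


class RunLog:
    """Collects processing notes; writes them immediately when a path is given.

    Tests and callers can inspect :attr:`entries` (list of ``(level, message)``
    tuples) without reading the file back.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.entries: list[tuple[str, str]] = []
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("", encoding="utf-8")

    def _emit(self, level: str, message: str) -> None:
        self.entries.append((level, message))
        if self.path is not None:
            stamp = _dt.datetime.now().strftime("%Y-%m-%d %H:%M:%S")
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(f"{stamp}\t{level}\t{message}\n")

    def info(self, message: str) -> None:
        self._emit("INFO", message)

    def warn(self, message: str) -> None:
        self._emit("WARN", message)

    def error(self, message: str) -> None:
        self._emit("ERROR", message)

    def messages(self, level: str | None = None) -> list[str]:
        return [m for lv, m in self.entries if level is None or lv == level]
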