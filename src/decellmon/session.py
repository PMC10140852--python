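"""Session directories: ISO-8601-named, manifest-tracked, never overwritten.

Every run writes into a fresh directory whose name is the UTC creation
timestamp, with ``frames/``, ``traces/`` and ``plots/`` subdirectories, a
``manifest.json`` listing every result file, and a plain-text log that
captures the full configuration snapshot and seed for reproducibility.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import RunConfig

__all__ = ["Session", "SessionManifest", "create_session"]

SUBDIRS = ("frames", "traces", "plots")


@dataclass
class SessionManifest:
    created_at: str
    config: dict
    tool_version: str
    files: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "created_at": self.created_at,
            "config": self.config,
            "tool_version": self.tool_version,
            "files": list(self.files),
        }


@dataclass
class Session:
    directory: Path
    manifest: SessionManifest
    logger: logging.Logger

    @property
    def manifest_path(self) -> Path:
        return self.directory / "manifest.json"

    def write_manifest(self) -> None:
        self.manifest_path.write_text(
            json.dumps(self.manifest.to_dict(), indent=2) + "\n"
        )

    def record_file(self, path: Path) -> Path:
        """Register a result file in the manifest (relative to the session)."""
        rel = str(Path(path).relative_to(self.directory))
        if rel not in self.manifest.files:
            self.manifest.files.append(rel)
            self.write_manifest()
        return Path(path)

    def path(self, *parts: str) -> Path:
        return self.directory.joinpath(*parts)


def create_session(config: RunConfig, now: _dt.datetime | None = None) -> Session:
    """Create a fresh session directory under ``config.output_dir``.

    The directory name is the ISO-8601 UTC timestamp (colon-free for
    filesystem safety); a collision with an existing directory appends
    ``-1``, ``-2``, ... so re-running never overwrites previous results.
    The manifest and log are written before any result file.
    """
    base = Path(config.output_dir)
    base.mkdir(parents=True, exist_ok=True)
    if now is None:
        now = _dt.datetime.now(_dt.timezone.utc)
    stamp = now.strftime("%Y-%m-%dT%H%M%SZ")
    directory = base / stamp
    suffix = 0
    while directory.exists():
        suffix += 1
        directory = base / f"{stamp}-{suffix}"
    directory.mkdir()
    for sub in SUBDIRS:
        (directory / sub).mkdir()

    manifest = SessionManifest(
        created_at=now.isoformat(),
        config=config.to_dict(),
        tool_version=__version__,
    )

    logger = logging.getLogger(f"decellmon.session.{directory.name}")
    logger.setLevel(logging.INFO)
    logger.propagate = False
    handler = logging.FileHandler(directory / "session.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers = [handler]

    session = Session(directory=directory, manifest=manifest, logger=logger)
    session.write_manifest()
    logger.info("session created: %s", directory)
    logger.info("tool version: %s", __version__)
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))
    logger.info("seed: %d", config.seed)
    return session
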