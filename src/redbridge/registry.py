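"""In-process mock of the target-registry API.

The real target platform exposes an authenticated HTTP API (token endpoint,
profile listing/creation, questionnaire submission).  This package ships an
in-process mock honouring the same contract — token-scoped center
workspaces, profiles-only visibility before import, sequential profile →
questionnaire creation — with optional JSON state persistence so that
separate pipeline runs (e.g. a reimport test) share registry state, and a
failure-injection hook for exercising retry behaviour.

Real connectivity and credential encryption are out of scope; the mock's
token endpoint returns a static token scoped to a named workspace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .dedup import RegistryProfile


class RegistryError(RuntimeError):
    """Permanent transport/contract failure."""


class TransientRegistryError(RegistryError):
    """Retryable failure (emulates temporary API unavailability)."""


class AuthError(RegistryError):
    pass


@dataclass
class MockRegistry:
    """State of one mock registry instance, optionally file-backed."""

    state_path: Path | None = None
    workspaces: dict[str, dict] = field(default_factory=dict)
    call_count: int = 0
    write_count: int = 0
    # failure plan: list of operation names that raise TransientRegistryError,
    # consumed one per matching call ("*" matches any operation)
    fail_queue: list[str] = field(default_factory=list)
    fail_permanently: bool = False

    def __post_init__(self) -> None:
        if self.state_path is not None:
            self.state_path = Path(self.state_path)
            if self.state_path.exists():
                raw = json.loads(self.state_path.read_text(encoding="utf-8"))
                self.workspaces = raw.get("workspaces", {})

    # -- auth ---------------------------------------------------------------

    def issue_token(self, center: str = "default") -> str:
        """Static short-lived token scoped to one center workspace."""
        self._tick("issue_token")
        return f"tok-{center}"

    def _workspace(self, token: str) -> dict:
        if not token.startswith("tok-"):
            raise AuthError(f"invalid token {token!r}")
        center = token[4:]
        return self.workspaces.setdefault(
            center, {"profiles": [], "questionnaires": [], "next_id": 1}
        )

    # -- API surface ---------------------------------------------------------

    def list_profiles(self, token: str) -> list[RegistryProfile]:
        """GET /profiles — profile metadata only, no clinical content."""
        self._tick("list_profiles")
        ws = self._workspace(token)
        return [RegistryProfile(**p) for p in ws["profiles"]]

    def create_profile(self, token: str, surname: str, given_name: str,
                       birth_date: str) -> str:
        """POST /profiles — returns the new profile_id."""
        self._tick("create_profile")
        ws = self._workspace(token)
        profile_id = f"P{ws['next_id']:06d}"
        ws["next_id"] += 1
        ws["profiles"].append({
            "profile_id": profile_id, "surname": surname,
            "given_name": given_name, "birth_date": birth_date,
        })
        self.write_count += 1
        self._persist()
        return profile_id

    def create_questionnaire(self, token: str, profile_id: str,
                             payload: dict) -> str:
        """POST /questionnaires — attaches a questionnaire response."""
        self._tick("create_questionnaire")
        ws = self._workspace(token)
        if not any(p["profile_id"] == profile_id for p in ws["profiles"]):
            raise RegistryError(f"unknown profile {profile_id}")
        qid = f"Q{len(ws['questionnaires']) + 1:06d}"
        ws["questionnaires"].append({"id": qid, "profile_id": profile_id,
                                     "payload": payload})
        self.write_count += 1
        self._persist()
        return qid

    # -- plumbing ------------------------------------------------------------

    def _tick(self, op: str) -> None:
        self.call_count += 1
        if self.fail_permanently:
            raise TransientRegistryError(f"{op}: service unavailable")
        if self.fail_queue and self.fail_queue[0] in ("*", op):
            self.fail_queue.pop(0)
            raise TransientRegistryError(f"{op}: service unavailable")

    def _persist(self) -> None:
        if self.state_path is not None:
            self.state_path.write_text(
                json.dumps({"workspaces": self.workspaces}, ensure_ascii=False),
                encoding="utf-8",
            )
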