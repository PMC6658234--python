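import json

import pytest

from forumlens.ingest import CommentRecord
from forumlens.synthetic import CommunityConfig, GeneratorConfig


def records_from_lines(lines):
    """Parse generator archive lines into CommentRecord objects."""
    out = []
    for line in lines:
        o = json.loads(line)
        out.append(
            CommentRecord(
                author=o["author"],
                forum=o["subreddit"],
                thread_id=o["link_id"],
                created_utc=o["created_utc"],
                body=o["body"],
            )
        )
    return out


@pytest.fixture
def small_config():
    """Two planted communities, two forums each; quick to generate."""
    return GeneratorConfig(
        communities=[
            CommunityConfig(forums=["alpha", "beta"], n_commenters=60),
            CommunityConfig(forums=["gamma", "delta"], n_commenters=60),
        ],
        cross_community_prob=0.05,
        threads_per_forum=10,
        recovery_rate=0.2,
        seed=7,
    )


@pytest.fixture
def write_archive_file(tmp_path):
    def _write(lines, name="archive.jsonl"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
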