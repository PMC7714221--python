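"""HTTP surfaces: native REST and refget, served from one repository."""

import json
import urllib.error
import urllib.request

import pytest

from seqvault.digests import compute_identifiers
from seqvault.rest import BackgroundServer


def _get(url):
    with urllib.request.urlopen(url) as resp:
        return resp.status, resp.read(), resp.headers.get("Content-Type")


def _status_of(url, method="GET"):
    req = urllib.request.Request(url, method=method)
    try:
        with urllib.request.urlopen(req) as resp:
            return resp.status
    except urllib.error.HTTPError as exc:
        return exc.code


@pytest.fixture
def server(loaded_repo):
    with BackgroundServer(loaded_repo) as srv:
        yield srv, loaded_repo


def test_ping_reports_repository_stats(server):
    srv, repo = server
    status, body, ctype = _get(srv.url + "/v1/ping")
    assert status == 200 and ctype == "application/json"
    doc = json.loads(body)
    assert doc["n_sequences"] == repo.stats().n_sequences
    assert doc["service_name"] and doc["version"]


def test_native_sequence_and_slices(server):
    srv, repo = server
    full = repo.fetch("test:SYN0011.00000")
    assert _get(srv.url + "/v1/sequence/test:SYN0011.00000")[1].decode() == full
    status, body, ctype = _get(srv.url + "/v1/sequence/test:SYN0011.00000?start=2&end=7")
    assert status == 200 and body.decode() == full[2:7]
    assert ctype == "text/plain"
    assert _get(srv.url + "/v1/sequence/test:SYN0011.00000?start=3&end=3")[1] == b""


def test_native_metadata_document(server):
    srv, repo = server
    _, body, _ = _get(srv.url + "/v1/metadata/test:SYN0011.00000")
    doc = json.loads(body)
    seq = repo.fetch("test:SYN0011.00000")
    assert doc["length"] == len(seq)
    assert doc["alphabet"] == "".join(sorted(set(seq)))
    assert "test:SYN0011.00000" in doc["aliases"]
    assert doc["aliases"] == sorted(doc["aliases"])
    assert doc["added"]


def test_native_error_codes(server):
    srv, repo = server
    base = srv.url + "/v1/sequence/"
    assert _status_of(base + "test:ABSENT") == 404
    assert _status_of(base + "test:SYN0011.00000?start=5&end=2") == 422
    assert _status_of(base + "test:SYN0011.00000?start=0&end=99999999") == 422
    assert _status_of(base + "test:SYN0011.00000?start=x") == 400
    assert _status_of(srv.url + "/v1/metadata/test:ABSENT") == 404


def test_ambiguous_bare_alias_lists_candidates(tmp_path):
    from seqvault.repo import SeqVault

    repo = SeqVault(tmp_path / "amb", writeable=True)
    repo.store("ACGTACGT", ["nsa:SHARED"])
    repo.store("TTTTAAAA", ["nsb:SHARED"])
    repo.commit()
    with BackgroundServer(repo) as srv:
        req = urllib.request.Request(srv.url + "/v1/sequence/SHARED")
        with pytest.raises(urllib.error.HTTPError) as exc:
            urllib.request.urlopen(req)
        assert exc.value.code == 422
        body = exc.value.read().decode()
        assert "nsa" in body and "nsb" in body
    repo.close()


def test_refget_service_info(server):
    srv, _ = server
    _, body, _ = _get(srv.url + "/sequence/service-info")
    doc = json.loads(body)["service"]
    assert doc["circular_supported"] is False
    assert doc["subsequence_limit"] is None
    assert doc["supported_api_versions"]


def test_refget_accepts_all_digest_spellings(server):
    srv, repo = server
    seq = repo.fetch("test:SYN0011.00003")
    ids = compute_identifiers(seq)
    import base64, binascii

    trunc512 = binascii.hexlify(
        base64.urlsafe_b64decode(ids["sha512t24u"])
    ).decode()
    for digest in (ids["MD5"], ids["sha512t24u"], f"SQ.{ids['sha512t24u']}", trunc512):
        status, body, ctype = _get(srv.url + f"/sequence/{digest}")
        assert status == 200 and body.decode() == seq
        assert "refget" in ctype
    _, body, _ = _get(srv.url + f"/sequence/{ids['sha512t24u']}?start=0&end=4")
    assert body.decode() == seq[:4]


def test_refget_rejects_namespaced_identifiers(server):
    srv, _ = server
    assert _status_of(srv.url + "/sequence/test:SYN0011.00000") == 404


def test_refget_error_codes(server):
    srv, repo = server
    digest = repo._resolve("test:SYN0011.00000")
    assert _status_of(srv.url + f"/sequence/{digest}?start=0&end=99999999") == 416
    assert _status_of(srv.url + f"/sequence/{digest}?start=5&end=2") == 501
    assert _status_of(srv.url + f"/sequence/{digest}?start=-1") == 400
    assert _status_of(srv.url + "/sequence/" + "Q" * 32) == 404


def test_refget_metadata_document(server):
    srv, repo = server
    seq = repo.fetch("test:SYN0011.00001")
    ids = compute_identifiers(seq)
    _, body, _ = _get(srv.url + f"/sequence/{ids['sha512t24u']}/metadata")
    doc = json.loads(body)["metadata"]
    assert doc["md5"] == ids["MD5"]
    assert doc["length"] == len(seq)
    assert doc["ga4gh"] == f"SQ.{ids['sha512t24u']}"
    assert {"naming_authority": "test", "alias": "SYN0011.00001"} in doc["aliases"]


def test_only_get_is_accepted(server):
    srv, _ = server
    for method in ("POST", "PUT", "DELETE", "PATCH"):
        assert _status_of(srv.url + "/v1/sequence/test:SYN0011.00000", method) == 405
        assert _status_of(srv.url + "/v1/ping", method) == 405


def test_endpoints_respond_on_empty_repository(tmp_path):
    from seqvault.repo import SeqVault

    repo = SeqVault(tmp_path / "empty", writeable=True)
    with BackgroundServer(repo) as srv:
        assert _get(srv.url + "/v1/ping")[0] == 200
        assert _get(srv.url + "/sequence/service-info")[0] == 200
    repo.close()
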