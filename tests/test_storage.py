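import pytest

from dnastore import (
    METHOD_1_1CS,
    METHOD_1_MCI,
    METHOD_M_1CI,
    METHODS,
    StorageConfig,
    StoredFile,
    ToolBlob,
    ToolRegistry,
    build_plan,
    check_sharing_limit,
    get_codec,
    pool_payload_bits,
    store,
)
from dnastore.errors import SharingLimitError


def make_corpus(n_files=3, tool_bytes=240, file_bytes=200):
    registry = ToolRegistry()
    blob = bytes((i * 37) % 256 for i in range(tool_bytes))
    registry.register(101, "deflate", blob=blob)
    tools = [ToolBlob(101, "tool", blob, "deflate")]
    files = [StoredFile(i + 1, f"f{i}",
                        bytes((i + j) % 251 for j in range(file_bytes)),
                        101)
             for i in range(n_files)]
    return files, tools, registry


@pytest.fixture()
def corpus3(primer_pairs):
    files, tools, registry = make_corpus()
    return files, tools, registry


class TestSharingLimit:
    def test_paper_bound_holds_inside(self):
        assert check_sharing_limit(10, 220, 20)

    def test_boundary_excluded(self):
        assert not check_sharing_limit(11, 220, 20)

    def test_zero_excluded(self):
        assert not check_sharing_limit(0, 220, 20)

    def test_limit_error_on_store(self, primer_pairs):
        files, tools, registry = make_corpus(n_files=11, file_bytes=40)
        from dnastore import generate_primer_library
        pairs = generate_primer_library(12, seed=2)
        plan = build_plan(METHOD_1_MCI, files, tools, pairs)
        with pytest.raises(SharingLimitError):
            store(METHOD_1_MCI, files, tools, plan, StorageConfig(),
                  registry)


def decoded_tool_copies(result, plan, tools, config):
    """Count occurrences of the tool blob in the decoded pool payloads."""
    codec = get_codec(config.codec_name)
    blob = tools[0].blob
    copies = 0
    # decode every stream via the manifest and scan for the blob bytes
    from dnastore.fragments import Fragment, FragmentLayout, ROLE_DATA, \
        ROLE_MCI_TOOL, assemble
    manifest = result.manifest
    for fid, info in manifest.files.items():
        pair = plan.file_primers[fid]
        layout = FragmentLayout(manifest.L_s, manifest.L_p, info.l_addr,
                                manifest.rs_len, ROLE_DATA)
        frags = [Fragment.parse(r, layout) for r in result.pool
                 if r.startswith(pair.forward.sequence)]
        seq, _ = assemble(frags, data_nt=info.nt_length)
        raw = codec.decode(seq[:info.nt_length - info.pointer_nt])
        copies += raw.count(blob)
    for tfid, info in manifest.tools.items():
        if manifest.method == METHOD_M_1CI:
            head = plan.tool_primers[tfid].forward.sequence
            layout = FragmentLayout(manifest.L_s, manifest.L_p,
                                    info.l_addr, manifest.rs_len,
                                    ROLE_DATA)
        else:
            head = plan.universal.forward.sequence
            layout = FragmentLayout(manifest.L_s, manifest.L_p,
                                    info.l_addr, manifest.rs_len,
                                    ROLE_MCI_TOOL, info.n_shared)
        frags = [Fragment.parse(r, layout) for r in result.pool
                 if r.startswith(head)]
        _, seq = assemble(frags, tool_nt=info.nt_length)
        copies += codec.decode(seq).count(blob)
    return copies


class TestToolCopyCounts:
    def test_continuous_storage_duplicates_tool(self, corpus3,
                                                primer_pairs, config):
        files, tools, registry = corpus3
        plan = build_plan(METHOD_1_1CS, files, tools, primer_pairs)
        result = store(METHOD_1_1CS, files, tools, plan, config, registry)
        assert decoded_tool_copies(result, plan, tools, config) == 3

    @pytest.mark.parametrize("method", [METHOD_M_1CI, METHOD_1_MCI])
    def test_separate_storage_keeps_one_copy(self, corpus3, primer_pairs,
                                             config, method):
        files, tools, registry = corpus3
        plan = build_plan(method, files, tools, primer_pairs)
        result = store(method, files, tools, plan, config, registry)
        assert decoded_tool_copies(result, plan, tools, config) == 1


class TestM1CIPointer:
    def test_data_stream_ends_with_tool_primer_pointer(self, corpus3,
                                                       primer_pairs,
                                                       config):
        files, tools, registry = corpus3
        plan = build_plan(METHOD_M_1CI, files, tools, primer_pairs)
        result = store(METHOD_M_1CI, files, tools, plan, config, registry)
        from dnastore.fragments import Fragment, FragmentLayout, assemble
        tp = plan.tool_primers[101]
        for fid, info in result.manifest.files.items():
            pair = plan.file_primers[fid]
            layout = FragmentLayout(config.L_s, config.L_p, info.l_addr)
            frags = [Fragment.parse(r, layout) for r in result.pool
                     if r.startswith(pair.forward.sequence)]
            seq, _ = assemble(frags, data_nt=info.nt_length)
            pointer = seq[-info.pointer_nt:]
            assert pointer == tp.forward.sequence + tp.reverse.sequence


class TestMCIPrimerPlacement:
    def test_tool_fragments_carry_universal_and_client_reverses(
            self, primer_pairs, config):
        files, tools, registry = make_corpus(n_files=2)
        plan = build_plan(METHOD_1_MCI, files, tools, primer_pairs)
        result = store(METHOD_1_MCI, files, tools, plan, config, registry)
        uni = plan.universal.forward.sequence
        rev1 = plan.file_primers[1].reverse.sequence
        rev2 = plan.file_primers[2].reverse.sequence
        tool_frags = [r for r in result.pool if r.startswith(uni)]
        assert tool_frags
        for frag in tool_frags:
            assert uni in frag and rev1 in frag and rev2 in frag

    def test_single_file_single_tool_round_trips(self, primer_pairs,
                                                 config):
        files, tools, registry = make_corpus(n_files=1)
        plan = build_plan(METHOD_1_MCI, files, tools, primer_pairs)
        result = store(METHOD_1_MCI, files, tools, plan, config, registry)
        from dnastore import retrieve
        out = retrieve(result.pool, 1, result.manifest, plan, registry)
        assert out.data == files[0].data


class TestPayloadBitOrdering:
    def test_separate_storage_never_stores_more_bits(self, corpus3,
                                                     primer_pairs,
                                                     config):
        files, tools, registry = corpus3
        bits = {}
        for method in METHODS:
            plan = build_plan(method, files, tools, primer_pairs)
            result = store(method, files, tools, plan, config, registry)
            bits[method] = pool_payload_bits(result, plan)
        assert bits[METHOD_1_MCI] <= bits[METHOD_M_1CI]
        assert bits[METHOD_1_MCI] <= bits[METHOD_1_1CS]

    def test_empty_corpus_gives_empty_pool(self, config):
        registry = ToolRegistry()
        plan = build_plan(METHOD_1_1CS, [], [], [])
        result = store(METHOD_1_1CS, [], [], plan, config, registry)
        assert len(result.pool) == 0

    def test_of_file_round_trips_without_tool(self, primer_pairs, config):
        registry = ToolRegistry()
        files = [StoredFile(1, "raw", b"\x00\x01\x02hello", None)]
        plan = build_plan(METHOD_1_1CS, files, [], primer_pairs)
        result = store(METHOD_1_1CS, files, [], plan, config, registry)
        from dnastore import retrieve
        out = retrieve(result.pool, 1, result.manifest, plan, registry)
        assert out.data == files[0].data
        assert out.sequencing_rounds == 1
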