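"""Template CSV reading, reason parsing, validation and the example generator."""

import dataclasses
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prismaflow as pf
from prismaflow.flow_data import (
    COLUMNS,
    COUNT_DATA_KEYS,
    CountParseError,
    DuplicateKeyError,
    PLACEHOLDER,
    ReasonParseError,
    SchemaError,
)


# ---------------------------------------------------------------------------
# Reading and round-tripping
# ---------------------------------------------------------------------------


class TestReadTemplate:
    def test_blank_template_shape_and_known_cells(self, blank_fd):
        assert len(blank_fd.rows) == 30
        assert len(blank_fd.by_key) == 27  # 24 count keys + 3 bar rows
        row = blank_fd.by_key["previous_studies"]
        assert row.boxtext == "Studies included in previous version of review"
        assert row.node_id == "node5"
        assert row.box_id == "box 1"
        assert blank_fd.by_key["dbr_excluded"].boxtext == "Reports excluded:"
        assert blank_fd.by_key["dbr_sought_reports"].boxtext == "Reports sought for retrieval"

    def test_na_and_empty_cells_both_mean_absent(self):
        text = ",".join(COLUMNS) + "\n" + "duplicates,NA,box 3,,Duplicate records,NA,,5\n"
        fd = pf.read_template(io.StringIO(text))
        row = fd.by_key["duplicates"]
        assert row.node_id is None
        assert row.description is None
        assert row.tooltip is None
        assert row.url is None
        assert row.count == 5

    def test_header_only_file_reads_empty_not_error(self, full_config):
        fd = pf.read_template(io.StringIO(",".join(COLUMNS) + "\n"))
        assert fd.rows == ()
        # missing rows are a validation concern, not a read error
        assert not pf.validate(fd, full_config).ok

    @pytest.mark.parametrize(
        "text, exc, fragment",
        [
            ("data,node,box,description,boxtext,tooltips,hyperlink,n\nx,NA,b,NA,t,NA,NA,1\n",
             SchemaError, "url"),
            ("data,node,box\nx,NA,b\n", SchemaError, "description"),
            (",".join(COLUMNS) + ",extra\n" + "x,NA,b,NA,t,NA,NA,1,y\n",
             SchemaError, "extra"),
            (",".join(COLUMNS) + "\nx,NA,b,NA,t,NA,NA\n", SchemaError, "field"),
            (",".join(COLUMNS) + "\nx,NA,b,NA,t,NA,NA,1\nx,NA,b,NA,t,NA,NA,2\n",
             DuplicateKeyError, "x"),
            ("", SchemaError, "header"),
        ],
    )
    def test_schema_violations_are_named(self, text, exc, fragment):
        with pytest.raises(exc, match=fragment):
            pf.read_template(io.StringIO(text))

    def test_blank_template_roundtrip_is_byte_identical(self):
        text = pf.generate_blank_template()
        assert pf.write_template(pf.read_template(io.StringIO(text))) == text

    def test_shipped_resource_matches_generator(self):
        from importlib import resources

        shipped = (
            resources.files("prismaflow")
            .joinpath("data/prisma2020_template.csv")
            .read_text(encoding="utf-8")
        )
        assert shipped == pf.generate_blank_template()

    @settings(deadline=None, max_examples=50)
    @given(
        boxtext=st.text(
            alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
            min_size=0, max_size=40,
        ),
        url=st.none() | st.text(alphabet="abc:/#.", min_size=1, max_size=20),
        n=st.none() | st.integers(min_value=0, max_value=10**6).map(str),
    )
    def test_arbitrary_templates_roundtrip_field_level(self, boxtext, url, n):
        """write -> read preserves every field, including CSV-hostile text."""
        base = pf.blank_template()
        rows = list(base.rows)
        rows[1] = dataclasses.replace(rows[1], boxtext=boxtext, url=url, n_raw=n)
        fd = pf.FlowData(rows=tuple(rows))
        back = pf.read_template(io.StringIO(pf.write_template(fd)))
        # NA-in-text collapses to absent by design; skip that alias
        if boxtext.strip() != "NA":
            assert back.rows[1].boxtext == boxtext
        assert back.rows[1].url == url
        assert back.rows[1].n_raw == n


# ---------------------------------------------------------------------------
# Reason parsing
# ---------------------------------------------------------------------------


def _oracle_split(raw):
    """Independent split-and-trim reference for the reason grammar."""
    out = []
    for seg in raw.split(";"):
        seg = seg.strip()
        if not seg:
            continue
        if "," in seg:
            head, tail = seg.rsplit(",", 1)
            out.append((head.strip(), tail.strip()))
        else:
            out.append(("", seg))
    return out


class TestParseReasons:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (
                "Reason1, xxx; Reason2, xxx; Reason3, xxx",
                [("Reason1", PLACEHOLDER), ("Reason2", PLACEHOLDER), ("Reason3", PLACEHOLDER)],
            ),
            ("", []),
            ("Wrong population, 15; Wrong outcome, 7",
             [("Wrong population", 15), ("Wrong outcome", 7)]),
            ("42", [("", 42)]),
            ("Too old, too small, 3", [("Too old, too small", 3)]),
            ("a, 1; ; b, 2", [("a", 1), ("b", 2)]),
        ],
    )
    def test_grammar_cases(self, raw, expected):
        assert list(pf.parse_reasons(raw).reasons) == expected

    def test_unparseable_segment_is_identified(self):
        with pytest.raises(ReasonParseError, match="banana"):
            pf.parse_reasons("Wrong population, 5; banana")

    @settings(deadline=None, max_examples=300)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="abc ,x-", min_size=1, max_size=15).filter(
                    lambda s: s.strip()
                ),
                st.integers(min_value=0, max_value=9999),
            ),
            min_size=0,
            max_size=6,
        )
    )
    def test_matches_split_and_trim_oracle(self, pairs):
        raw = "; ".join(f"{label}, {count}" for label, count in pairs)
        parsed = pf.parse_reasons(raw)
        oracle = _oracle_split(raw)
        assert len(parsed) == len(oracle)
        for (lab, cnt), (olab, ocnt) in zip(parsed.reasons, oracle):
            assert lab == olab
            assert str(cnt) == ocnt


class TestParseCount:
    def test_shapes(self):
        from prismaflow.flow_data import parse_count

        assert parse_count(None) is None
        assert parse_count("NA") is None
        assert parse_count("xxx") == PLACEHOLDER
        assert parse_count("17") == 17
        assert len(parse_count("a, 1; b, 2")) == 2
        with pytest.raises(CountParseError):
            parse_count("seventeen")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


class TestValidate:
    def test_example_data_full_config_clean(self, example_fd, full_config):
        report = pf.validate(example_fd, full_config, strict=True)
        assert report.errors == []
        assert report.warnings == []

    def test_blank_template_draft_warnings_only(self, blank_fd, full_config):
        report = pf.validate(blank_fd, full_config, strict=False)
        assert report.errors == []
        assert report.warnings  # every count is a placeholder
        assert all("placeholder" in msg for _, msg in report.warnings)

    def test_blank_template_strict_rejects_placeholders(self, blank_fd, full_config):
        report = pf.validate(blank_fd, full_config, strict=True)
        assert any("placeholder" in msg for _, msg in report.errors)

    def test_missing_row_named_in_error(self, blank_fd, full_config):
        rows = tuple(r for r in blank_fd.rows if r.data_key != "duplicates")
        report = pf.validate(pf.FlowData(rows=rows), full_config)
        assert any(ref == "duplicates" for ref, _ in report.errors)

    def test_arm_keys_not_required_when_arm_disabled(self, blank_fd):
        rows = tuple(
            r for r in blank_fd.rows
            if r.data_key not in {"total_studies", "total_reports"}
        )
        fd = pf.FlowData(rows=rows)
        assert not pf.validate(fd, pf.ArmConfig(include_previous=True)).ok
        assert pf.validate(fd, pf.ArmConfig(include_previous=False)).ok

    def test_negative_count_is_error(self, example_fd, full_config):
        fd = example_fd.with_counts({"duplicates": "-3"})
        report = pf.validate(fd, full_config)
        assert any("negative" in msg for _, msg in report.errors)

    def test_malformed_url_is_error(self, example_fd, full_config):
        rows = list(example_fd.rows)
        idx = next(i for i, r in enumerate(rows) if r.data_key == "records_screened")
        rows[idx] = dataclasses.replace(rows[idx], url="has space.html")
        report = pf.validate(pf.FlowData(rows=tuple(rows)), full_config)
        assert any("url" in msg for _, msg in report.errors)

    def test_inconsistent_arithmetic_warns_never_errors(self, example_fd, full_config):
        screened = example_fd.by_key["records_screened"].count
        fd = example_fd.with_counts({"records_screened": str(screened + 1)})
        report = pf.validate(fd, full_config)
        assert report.errors == []
        assert any(ref == "records_screened" for ref, _ in report.warnings)


# ---------------------------------------------------------------------------
# Example-data generator
# ---------------------------------------------------------------------------


class TestGenerateExampleData:
    def test_same_seed_same_data(self):
        assert pf.generate_example_data(1) == pf.generate_example_data(1)
        assert pf.generate_example_data(1) != pf.generate_example_data(2)

    @pytest.mark.parametrize("seed", [1, 7, 123])
    def test_counts_satisfy_stage_accounting(self, seed):
        fd = pf.generate_example_data(seed)
        v = lambda k: fd.by_key[k].count  # noqa: E731
        identified = v("database_results") + v("register_results")
        removed = v("duplicates") + v("excluded_automatic") + v("excluded_other")
        assert v("records_screened") == identified - removed
        assert v("dbr_sought_reports") == v("records_screened") - v("records_excluded")
        assert v("dbr_assessed") == v("dbr_sought_reports") - v("dbr_notretrieved_reports")
        assert v("total_studies") == v("previous_studies") + v("new_studies")
        # and the validator's own arithmetic oracle agrees
        report = pf.validate(fd, pf.ArmConfig(), strict=True)
        assert report.errors == [] and report.warnings == []

    def test_exclusion_boxes_carry_named_reasons(self, example_fd):
        for key in ("dbr_excluded", "other_excluded"):
            breakdown = example_fd.by_key[key].count
            assert 2 <= len(breakdown) <= 4
            assert all(label for label, _ in breakdown.reasons)

    @pytest.mark.parametrize("config", [pf.ArmConfig(p, o) for p in (True, False) for o in (True, False)])
    def test_renders_in_every_arm_configuration(self, example_fd, config):
        doc = pf.render_svg(pf.layout(pf.build_graph(example_fd, config)))
        assert doc.content.startswith("<?xml")


# ---------------------------------------------------------------------------
# The editable surface
# ---------------------------------------------------------------------------


def test_structural_columns_do_not_affect_output(example_fd, full_config):
    """Only boxtext/tooltips/url/n feed the diagram; the node, box and
    description columns are documentation."""
    reference = pf.render_svg(pf.layout(pf.build_graph(example_fd, full_config)))
    rows = tuple(
        dataclasses.replace(
            r,
            description="rewritten",
            node_id=f"zz{i}" if r.node_id else None,
        )
        for i, r in enumerate(example_fd.rows)
    )
    mutated = pf.FlowData(rows=rows)
    got = pf.render_svg(pf.layout(pf.build_graph(mutated, full_config)))
    assert got.content == reference.content
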