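"""Readers and writers for the corpus XML dialect and external assessments.

The corpus dialect is a flat, self-describing structure::

    <corpus>
      <episode id="17">
        <administration day="0"/> ...
        <observation day="-6" value="0.481203"/> ...
        <classification call="no_change" agree_count="9" n_raters="11"
                        concordance="0.818182" intricacy="medium"
                        standoff="false"/>
        <vote rater="r01" category="no_change"/> ...   (optional)
      </episode>
    </corpus>

Administration and observation days are relative (day 0 = first
administration day); observation values are reference-interval
normalized and serialized with six decimal places. Raw votes are
optional because ground-truth corpora may ship the aggregated
classification only. Output is deterministic: identical corpora produce
byte-identical files.

External assessments (one category per episode id, as produced by any
external rater or algorithm) use::

    <assessment assessor="my_algorithm">
      <entry episode="17" category="no_change"/> ...
    </assessment>
"""

from __future__ import annotations

import os
from fractions import Fraction

from lxml import etree

from labtempo.model import (
    CATEGORIES,
    AssessmentSet,
    Classification,
    Corpus,
    Episode,
    NormalizedPoint,
    ValidationError,
    VoteSet,
    validate_corpus,
)

_VALUE_FMT = "{:.6f}"


def _parse_error(path: str, exc: etree.XMLSyntaxError) -> ValidationError:
    return ValidationError(f"{path}: malformed XML: {exc}")


def _attr(element: etree._Element, name: str) -> str:
    value = element.get(name)
    if value is None:
        raise ValidationError(
            f"<{element.tag}> element missing required attribute {name!r}"
        )
    return value


def write_corpus(corpus: Corpus, path: str | os.PathLike) -> None:
    """Serialize a corpus; byte-stable for identical input."""
    root = etree.Element("corpus")
    votes_by_id: dict[str, VoteSet] = {}
    if corpus.raw_votes is not None:
        votes_by_id = {v.episode_id: v for v in corpus.raw_votes}
    classifications = {c.episode_id: c for c in corpus.classifications}
    for episode in corpus.episodes:
        el = etree.SubElement(root, "episode", id=episode.episode_id)
        if episode.truth_label is not None:
            el.set("truth", "1" if episode.truth_label else "0")
        if episode.parameter_tag is not None:
            el.set("parameter", episode.parameter_tag)
        for day in sorted(episode.administration_days):
            etree.SubElement(el, "administration", day=str(day))
        for point in episode.points:
            etree.SubElement(
                el,
                "observation",
                day=str(point.relative_day),
                value=_VALUE_FMT.format(point.value),
            )
        cls = classifications.get(episode.episode_id)
        if cls is not None:
            etree.SubElement(
                el,
                "classification",
                call=cls.call,
                agree_count=str(cls.agree_count),
                n_raters=str(cls.n_raters),
                concordance=_VALUE_FMT.format(cls.concordance),
                intricacy=cls.intricacy,
                standoff="true" if cls.standoff else "false",
            )
        votes = votes_by_id.get(episode.episode_id)
        if votes is not None:
            for rater, category in votes.votes:
                etree.SubElement(el, "vote", rater=rater, category=category)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_corpus(path: str | os.PathLike, validate: bool = True) -> Corpus:
    """Parse and validate a corpus file.

    Raises :class:`ValidationError` with the episode id and violated
    rule when an episode fails structural validation, and a parse error
    with line information on malformed XML.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise _parse_error(str(path), exc) from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise ValidationError(f"{path}: root element is <{root.tag}>, not <corpus>")
    episodes: list[Episode] = []
    classifications: list[Classification] = []
    votes: list[VoteSet] = []
    any_votes = False
    for el in root.iterfind("episode"):
        episode_id = _attr(el, "id")
        admin_days = frozenset(
            int(_attr(a, "day")) for a in el.iterfind("administration")
        )
        points = tuple(
            NormalizedPoint(int(_attr(o, "day")), float(_attr(o, "value")))
            for o in el.iterfind("observation")
        )
        truth = el.get("truth")
        episodes.append(
            Episode(
                episode_id=episode_id,
                administration_days=admin_days,
                points=points,
                truth_label=None if truth is None else truth == "1",
                parameter_tag=el.get("parameter"),
            )
        )
        cls_el = el.find("classification")
        if cls_el is not None:
            agree = int(_attr(cls_el, "agree_count"))
            n_raters = int(_attr(cls_el, "n_raters"))
            call = _attr(cls_el, "call")
            if call not in CATEGORIES:
                raise ValidationError(
                    f"episode {episode_id}: unknown call {call!r}"
                )
            classifications.append(
                Classification(
                    episode_id=episode_id,
                    call=call,
                    # exact ratio, not the rounded serialized value
                    concordance=float(Fraction(agree, n_raters)),
                    agree_count=agree,
                    n_raters=n_raters,
                    intricacy=_attr(cls_el, "intricacy"),
                    standoff=_attr(cls_el, "standoff") == "true",
                )
            )
        vote_els = list(el.iterfind("vote"))
        if vote_els:
            any_votes = True
            votes.append(
                VoteSet(
                    episode_id=episode_id,
                    votes=tuple(
                        (_attr(v, "rater"), _attr(v, "category")) for v in vote_els
                    ),
                )
            )
    corpus = Corpus(
        episodes=episodes,
        classifications=classifications,
        raw_votes=votes if any_votes else None,
    )
    if validate:
        validate_corpus(corpus)
    return corpus


def write_external_assessment(assessment: AssessmentSet, path: str | os.PathLike) -> None:
    root = etree.Element("assessment", assessor=assessment.assessor_id)
    for episode_id in sorted(assessment.entries, key=_episode_sort_key):
        etree.SubElement(
            root, "entry", episode=episode_id, category=assessment.entries[episode_id]
        )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_external_assessment(path: str | os.PathLike) -> AssessmentSet:
    """Parse an external assessment (one category per episode id)."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise _parse_error(str(path), exc) from exc
    root = tree.getroot()
    if root.tag != "assessment":
        raise ValidationError(
            f"{path}: root element is <{root.tag}>, not <assessment>"
        )
    entries: dict[str, str] = {}
    for el in root.iterfind("entry"):
        episode_id = _attr(el, "episode")
        category = _attr(el, "category")
        if episode_id in entries:
            raise ValidationError(
                f"{path}: duplicate entry for episode {episode_id}"
            )
        if category not in CATEGORIES:
            raise ValidationError(
                f"{path}: episode {episode_id} has unknown category {category!r}"
            )
        entries[episode_id] = category
    return AssessmentSet(assessor_id=root.get("assessor", "external"), entries=entries)


def _episode_sort_key(episode_id: str):
    # numeric ids sort numerically, anything else lexically after them
    try:
        return (0, int(episode_id), "")
    except ValueError:
        return (1, 0, episode_id)
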