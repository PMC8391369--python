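"""Seeded synthetic inputs: profiles, evaluation dialogue sets, transcripts.

Everything the system needs to be exercised end-to-end is generated here,
deterministically per seed: fully answered patient profiles with plausible
Mexican-Spanish values, rule-based simulated users that sustain a
conversation in a given context, the 40-dialogue static-context evaluation
set (two dialogues for each of the 20 contexts, four candidate responses
each), synthetic evaluator votes, and reference/hypothesis transcript
pairs corrupted at configurable substitution/insertion/deletion rates.

The simulated user is rule-based (affirmations, topic mentions, echoes of
the profile's own slot values), not a language model, so fixture
generation is fully deterministic and offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Mapping, Sequence

from .dialogue import LEAVE_CONTEXT, OPENING_CONTEXT, DialogueEngine
from .errors import InsufficientKBError, RangeError
from .evaluation import EvaluationDialogue, VoteTable
from .kb import KnowledgeBase, select_and_render
from .normalize import normalize
from .profiles import FamilyMember, PatientProfile, build_profile, default_schema

__all__ = [
    "FixtureConfig",
    "generate_profile",
    "simulated_user",
    "generate_evaluation_set",
    "generate_votes",
    "generate_transcript_pairs",
    "save_evaluation_set",
    "load_evaluation_set",
]

_FIXTURE_CREATED_AT = "2021-03-10T00:00:00+00:00"


@dataclass(frozen=True)
class FixtureConfig:
    """Evaluation-design parameters; the defaults reproduce the study
    design of two dialogues per context over the 20-context KB, at least
    four turns each and four candidate responses."""

    seed: int = 0
    n_dialogues_per_context: int = 2
    min_turns: int = 4
    n_candidates: int = 4
    locale: str = "es"

    def __post_init__(self) -> None:
        if self.n_candidates != 4:
            raise ValueError("the evaluation design uses exactly 4 candidates")
        if self.min_turns < 4:
            raise ValueError("dialogues need at least 4 turns")


# ---------------------------------------------------------------------------
# profile generation
# ---------------------------------------------------------------------------

_NAMES_F = ["María", "Guadalupe", "Carmen", "Josefina", "Teresa", "Rosa",
            "Patricia", "Leticia", "Elena", "Margarita", "Dolores", "Silvia"]
_NAMES_M = ["José", "Juan", "Francisco", "Antonio", "Miguel", "Pedro",
            "Jorge", "Manuel", "Rafael", "Alberto", "Ernesto", "Raúl"]
_KIN_F = ["hija", "esposa", "nieta", "hermana", "sobrina"]
_KIN_M = ["hijo", "esposo", "nieto", "hermano", "sobrino"]
_PLACES = ["Puebla", "Guadalajara", "Oaxaca", "Mérida", "Morelia",
           "Veracruz", "Querétaro", "Zacatecas", "San Luis Potosí"]
_VISITED = ["Acapulco", "la Ciudad de México", "Veracruz", "las pirámides de Teotihuacán",
            "la basílica de Guadalupe", "Cancún", "el puerto de Mazatlán"]
_PROFESSIONS = ["maestra", "carpintero", "costurera", "comerciante", "agricultor",
                "enfermera", "panadero", "secretaria"]
_HABITS = ["caminar por el parque", "regar las plantas", "leer el periódico",
           "tejer por las tardes", "escuchar la radio"]
_SKILLS = ["tejer", "dibujar", "cantar", "la carpintería", "bordar", "cocinar"]
_HOBBIES = ["el dominó", "la lotería", "bailar danzón", "la jardinería", "jugar a la baraja"]
_CHORES = ["cocinar", "regar el jardín", "barrer el patio", "hornear pan"]
_MOVIES = ["Nosotros los pobres", "El padrecito", "Macario", "María Candelaria",
           "Allá en el Rancho Grande"]
_TV = ["Siempre en domingo", "El Chavo del 8", "La carabina de Ambrosio", "las telenovelas"]
_ACTORS = ["Pedro Infante", "María Félix", "Cantinflas", "Dolores del Río", "Jorge Negrete"]
_MUSIC = ["ranchera", "los boleros", "el danzón", "los tríos", "el mariachi"]
_SINGERS = ["Pedro Infante", "Javier Solís", "Lola Beltrán", "Los Panchos", "José Alfredo Jiménez"]
_SPORTS = ["fútbol", "béisbol", "box", "lucha libre"]
_TEAMS = ["el Puebla", "las Chivas", "el América", "los Pumas", "Cruz Azul"]
_DISHES = ["el mole poblano", "los chiles en nogada", "el pozole", "los tamales",
           "las enchiladas verdes"]
_DRINKS = ["el café de olla", "el atole", "el agua de jamaica", "el chocolate caliente"]
_FESTIVITIES = ["la Navidad", "el Día de Muertos", "las posadas", "la feria del pueblo"]
_MEMORIES = ["jugar en el río con mis hermanos", "las ferias del pueblo",
             "ayudar a mi madre en la cocina", "ir al mercado los domingos"]


def generate_profile(seed: int) -> PatientProfile:
    """A fully answered 32-slot profile with 1-3 family members.

    Deterministic per seed; different seeds differ in at least one slot
    with overwhelming probability given the value pools.
    """
    rng = Random(seed)
    schema = default_schema()
    female = rng.random() < 0.5
    name = rng.choice(_NAMES_F if female else _NAMES_M)
    birth_year = rng.randint(1936, 1956)
    n_children = rng.randint(1, 5)
    answers = {
        "patient_name": name,
        "apodo": ("Doña " if female else "Don ") + name,
        "fecha_nacimiento": f"{rng.randint(1, 28)}/{rng.randint(1, 12)}/{birth_year}",
        "lugar_nacimiento": rng.choice(_PLACES),
        "edad": str(2021 - birth_year),
        "genero": "femenino" if female else "masculino",
        "estado_civil": rng.choice(["casada", "viuda", "soltera"] if female
                                   else ["casado", "viudo", "soltero"]),
        "profesion": rng.choice(_PROFESSIONS),
        "escolaridad": rng.choice(["primaria", "secundaria", "preparatoria"]),
        "lugar_residencia": rng.choice(_PLACES),
        "idioma_materno": "español",
        "numero_hijos": str(n_children),
        "nombre_conyuge": rng.choice(_NAMES_M if female else _NAMES_F),
        "nombre_madre": rng.choice(_NAMES_F),
        "nombre_padre": rng.choice(_NAMES_M),
        "habito_diario": rng.choice(_HABITS),
        "habilidad_especial": rng.choice(_SKILLS),
        "pasatiempo_favorito": rng.choice(_HOBBIES),
        "tarea_hogar": rng.choice(_CHORES),
        "lugar_visitado": rng.choice(_VISITED),
        "pelicula_favorita": rng.choice(_MOVIES),
        "programa_favorito": rng.choice(_TV),
        "actor_favorito": rng.choice(_ACTORS),
        "musica_favorita": rng.choice(_MUSIC),
        "cantante_favorito": rng.choice(_SINGERS),
        "deporte_favorito": rng.choice(_SPORTS),
        "equipo_favorito": rng.choice(_TEAMS),
        "comida_favorita": rng.choice(_DISHES),
        "bebida_favorita": rng.choice(_DRINKS),
        "festividad_favorita": rng.choice(_FESTIVITIES),
        "recuerdo_infancia": rng.choice(_MEMORIES),
        "rutina_diaria": "desayunar temprano, " + rng.choice(_HABITS) + " y dormir una siesta",
    }
    family = []
    for i in range(1, rng.randint(1, 3) + 1):
        fem = rng.random() < 0.5
        family.append(
            FamilyMember(
                index=i,
                name=rng.choice(_NAMES_F if fem else _NAMES_M),
                relationship=rng.choice(_KIN_F if fem else _KIN_M),
            )
        )
    return build_profile(
        schema, answers, family,
        patient_id=f"pwad-sim-{seed}",
        created_at=_FIXTURE_CREATED_AT,
    )


# ---------------------------------------------------------------------------
# simulated user
# ---------------------------------------------------------------------------

#: How the simulated patient brings each topic up in conversation.
CONTEXT_MENTIONS: dict[str, str] = {
    "beginning_conversation": "hola",
    "leave_conversation": "adiós",
    "agent_profile": "¿quién eres?",
    "pwad_profile": "te quiero contar de mi cumpleaños",
    "family": "quiero platicar de mi familia",
    "habits": "tengo mis costumbres de siempre",
    "skills": "dicen que tengo habilidades",
    "hobbies": "tengo un pasatiempo que me encanta",
    "household_chores": "me gustaban los quehaceres",
    "visited_places": "me acuerdo de un viaje",
    "movies": "vamos a hablar de una película",
    "tv_shows": "me gustaba mucho la televisión",
    "actors": "había un actor muy bueno",
    "music": "extraño mucho la música de antes",
    "singers": "había un cantante que me gustaba",
    "sports": "de joven me gustaba el deporte",
    "sport_teams": "yo le iba a un equipo",
    "food_dishes": "vamos a platicar de comida",
    "beverages": "se me antoja una bebida",
    "festivities": "me acuerdo de las fiestas del pueblo",
}

#: The profile slot a context's customized templates revolve around.
CONTEXT_SLOT: dict[str, str] = {
    "pwad_profile": "lugar_nacimiento",
    "family": "fam1_name",
    "habits": "habito_diario",
    "skills": "habilidad_especial",
    "hobbies": "pasatiempo_favorito",
    "household_chores": "tarea_hogar",
    "visited_places": "lugar_visitado",
    "movies": "pelicula_favorita",
    "tv_shows": "programa_favorito",
    "actors": "actor_favorito",
    "music": "musica_favorita",
    "singers": "cantante_favorito",
    "sports": "deporte_favorito",
    "sport_teams": "equipo_favorito",
    "food_dishes": "comida_favorita",
    "beverages": "bebida_favorita",
    "festivities": "festividad_favorita",
}


def simulated_user(
    context_id: str,
    seed: int,
    profile: PatientProfile | None = None,
    n_utterances: int = 8,
) -> list[str]:
    """Deterministic utterance stream sustaining a conversation.

    The stream opens with the topic mention for ``context_id``, then
    alternates affirmations with an echo of the profile's topical slot
    value (for customized contexts), enough to sustain ``n_utterances``
    exchanges.
    """
    if context_id not in CONTEXT_MENTIONS:
        raise KeyError(f"unknown context {context_id!r}")
    rng = Random(seed)
    lines = [CONTEXT_MENTIONS[context_id]]
    fillers = ["sí", "sí claro", "sí cómo no"]
    softeners = ["no me acuerdo muy bien", "qué bonitos tiempos", "eso me gusta mucho"]
    slot = CONTEXT_SLOT.get(context_id)
    echo = None
    if slot and profile is not None:
        value = profile.get_slot(slot)
        if value:
            echo = f"me gusta {value}"
    lines.append(rng.choice(fillers))
    if echo:
        lines.append(echo)
    while len(lines) < n_utterances:
        lines.append(rng.choice(fillers + softeners))
    return lines[:n_utterances]


# ---------------------------------------------------------------------------
# evaluation set
# ---------------------------------------------------------------------------

def _distractors(
    kb: KnowledgeBase,
    profile: PatientProfile,
    true_context: str,
    true_response: str,
    rng: Random,
) -> list[str]:
    """Three fluent but off-topic candidates from other contexts."""
    other = [c for c in kb.contexts if c not in (true_context, LEAVE_CONTEXT)]
    rng.shuffle(other)
    out: list[str] = []
    for cid in other:
        cat = kb.intro_category(cid)
        if cat is None:
            continue
        rendered = select_and_render(kb, cat, profile, rng=Random(rng.randrange(2**31)))
        if rendered is None:
            continue
        text = rendered[0]
        if text != true_response and text not in out:
            out.append(text)
        if len(out) == 3:
            return out
    raise InsufficientKBError("could not assemble 3 distinct distractor responses")


def generate_evaluation_set(
    kb: KnowledgeBase,
    profile: PatientProfile,
    config: FixtureConfig = FixtureConfig(),
) -> list[EvaluationDialogue]:
    """Build the static-context evaluation set.

    For every context, ``n_dialogues_per_context`` dialogues are driven by
    the simulated user; each dialogue keeps at least ``min_turns``
    alternating turns ending on a user utterance, and its candidate list
    is the engine's true next response (position 0) plus three distractors
    rendered from other contexts.
    """
    engine = DialogueEngine(kb)
    dialogues: list[EvaluationDialogue] = []
    rng = Random(config.seed)
    for ci, context_id in enumerate(kb.contexts):
        for k in range(config.n_dialogues_per_context):
            session_seed = config.seed * 100_000 + ci * 100 + k
            session, _ = engine.start_session(profile, session_seed)
            script = list(
                simulated_user(context_id, session_seed, profile, n_utterances=12)
            )
            if context_id == LEAVE_CONTEXT:
                # chat a little before saying goodbye
                script = ["hola", "muy bien gracias", CONTEXT_MENTIONS[LEAVE_CONTEXT]]
            elif context_id == OPENING_CONTEXT:
                script = ["hola", "sí", "sí claro", "muy bien"]
            needed = config.min_turns + 1
            for line in script:
                engine.step(session, line)
                if len(session.transcript) > needed and session.transcript[-1].speaker == "system":
                    break
                if session.closed:
                    break
            if len(session.transcript) < needed or session.transcript[-1].speaker != "system":
                raise InsufficientKBError(
                    f"context {context_id!r} could not sustain {config.min_turns} turns"
                )
            turns = tuple(
                (t.speaker, t.raw_text) for t in session.transcript[:-1]
            )
            true_response = session.transcript[-1].raw_text
            candidates = [true_response] + _distractors(
                kb, profile, context_id, true_response, rng
            )
            dialogues.append(
                EvaluationDialogue(
                    dialogue_id=f"{context_id}-{k + 1}",
                    context_id=context_id,
                    turns=turns,
                    candidates=tuple(candidates),
                )
            )
    return dialogues


def generate_votes(
    dialogues: Sequence[EvaluationDialogue],
    n_evaluators: int = 11,
    seed: int = 0,
    weights: Sequence[float] = (0.55, 0.30, 0.10, 0.05),
) -> list[VoteTable]:
    """Synthetic bystander votes: one vote per evaluator per dialogue.

    The default preference weights emulate evaluators who usually judge
    the system's own response most appropriate, sometimes prefer the first
    distractor, and rarely the others.
    """
    rng = Random(seed)
    evaluators = [f"ev{i + 1:02d}" for i in range(n_evaluators)]
    tables = []
    for dlg in dialogues:
        votes = {
            ev: rng.choices(range(4), weights=weights)[0] for ev in evaluators
        }
        tables.append(VoteTable(dialogue_id=dlg.dialogue_id, votes=votes))
    return tables


# ---------------------------------------------------------------------------
# transcript pairs
# ---------------------------------------------------------------------------

_SENTENCES = [
    "Nací en un pueblo pequeño cerca de la capital en el año de mil novecientos cuarenta",
    "Mi madre preparaba mole todos los domingos y toda la familia venía a comer",
    "De joven me gustaba caminar por el campo con mis hermanos hasta el río",
    "Trabajé muchos años como maestra en la escuela primaria del barrio",
    "Los sábados íbamos al mercado a comprar fruta fresca y pan dulce",
    "Mi esposo y yo bailábamos danzón en la plaza principal cada fiesta",
    "Recuerdo con mucho cariño las posadas que hacíamos en diciembre",
    "Por las tardes me sentaba en el patio a tejer y escuchar la radio",
    "El equipo de mi ciudad ganó el campeonato y salimos todos a celebrar",
    "Cuando era niña ayudaba a mi abuela a regar las plantas del jardín",
    "Mi película favorita la vi en el cine del centro con mis primas",
    "Los lunes temprano íbamos a vender verdura al tianguis del pueblo",
    "Me gustaba mucho cantar canciones rancheras en las reuniones familiares",
    "Viajamos una vez a la costa y conocimos el mar por primera vez",
    "En la feria del pueblo siempre comprábamos algodón de azúcar y buñuelos",
]

_VOCAB = sorted({tok for s in _SENTENCES for tok in normalize(s).tokens})


def _corrupt(tokens: list[str], rates: Mapping[str, float], rng: Random) -> list[str]:
    def pick(exclude: set[str]) -> str:
        while True:
            w = rng.choice(_VOCAB)
            if w not in exclude:
                return w

    out: list[str] = []
    for i, tok in enumerate(tokens):
        if rng.random() < rates["del"]:
            continue
        if rng.random() < rates["sub"]:
            neighbors = {tok}
            if out:
                neighbors.add(out[-1])
            if i + 1 < len(tokens):
                neighbors.add(tokens[i + 1])
            tok = pick(neighbors)
        if out and out[-1] == tok:
            # avoid artifacts that the normalizer's repeat collapse would hide
            continue
        out.append(tok)
        if rng.random() < rates["ins"]:
            nxt = tokens[i + 1] if i + 1 < len(tokens) else ""
            out.append(pick({tok, nxt}))
    return out


def generate_transcript_pairs(
    seed: int,
    n_pairs: int,
    error_rates: Mapping[str, float] | None = None,
) -> list[tuple[str, str]]:
    """Reference/hypothesis pairs with controlled corruption.

    References are sampled Spanish sentences; hypotheses corrupt each
    token independently: deletion with probability ``del``, substitution
    by a different vocabulary word with probability ``sub``, and insertion
    of a random word after it with probability ``ins``.  All rates must
    lie in [0, 1].
    """
    rates = {"sub": 0.0, "ins": 0.0, "del": 0.0}
    rates.update(error_rates or {})
    for key, value in rates.items():
        if not 0.0 <= value <= 1.0:
            raise RangeError(f"rate {key}={value} outside [0, 1]")
    rng = Random(seed)
    pairs = []
    for _ in range(n_pairs):
        ref = rng.choice(_SENTENCES)
        hyp_tokens = _corrupt(list(normalize(ref).tokens), rates, rng)
        pairs.append((ref, " ".join(hyp_tokens)))
    return pairs


# ---------------------------------------------------------------------------
# JSON interface for evaluation sets
# ---------------------------------------------------------------------------

def save_evaluation_set(
    path: str | Path,
    dialogues: Sequence[EvaluationDialogue],
    config: FixtureConfig | None = None,
) -> None:
    doc = {
        "config": {
            "seed": config.seed,
            "n_dialogues_per_context": config.n_dialogues_per_context,
            "min_turns": config.min_turns,
            "n_candidates": config.n_candidates,
            "locale": config.locale,
        } if config else None,
        "dialogues": [d.to_dict() for d in dialogues],
    }
    Path(path).write_text(
        json.dumps(doc, ensure_ascii=False, indent=2) + "\n", encoding="utf-8"
    )


def load_evaluation_set(path: str | Path) -> list[EvaluationDialogue]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [EvaluationDialogue.from_dict(d) for d in doc["dialogues"]]
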