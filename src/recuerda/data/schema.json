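{
  "schema_id": "recuerda-cuestionario-v1",
  "description": "Cuestionario de personalización: información personal (11), relaciones familiares (4), historia de vida y estilo de vida (17).",
  "topics": [
    {
      "topic_id": "personal_information",
      "title": "Información personal",
      "questions": [
        {"slot_name": "patient_name", "prompt_text": "¿Cuál es el nombre del paciente?", "value_kind": "free_text", "required": true},
        {"slot_name": "apodo", "prompt_text": "¿Tiene algún apodo o sobrenombre con el que le gusta que le llamen?", "value_kind": "free_text"},
        {"slot_name": "fecha_nacimiento", "prompt_text": "¿Cuál es su fecha de nacimiento?", "value_kind": "date"},
        {"slot_name": "lugar_nacimiento", "prompt_text": "¿En qué lugar nació?", "value_kind": "free_text"},
        {"slot_name": "edad", "prompt_text": "¿Qué edad tiene?", "value_kind": "free_text"},
        {"slot_name": "genero", "prompt_text": "¿Cuál es su género?", "value_kind": "enum"},
        {"slot_name": "estado_civil", "prompt_text": "¿Cuál es su estado civil?", "value_kind": "enum"},
        {"slot_name": "profesion", "prompt_text": "¿Cuál fue su profesión u oficio?", "value_kind": "free_text"},
        {"slot_name": "escolaridad", "prompt_text": "¿Cuál es su nivel de estudios?", "value_kind": "free_text"},
        {"slot_name": "lugar_residencia", "prompt_text": "¿En qué lugar vive actualmente?", "value_kind": "free_text"},
        {"slot_name": "idioma_materno", "prompt_text": "¿Cuál es su idioma materno?", "value_kind": "free_text"}
      ]
    },
    {
      "topic_id": "family_relationships",
      "title": "Relaciones familiares",
      "questions": [
        {"slot_name": "numero_hijos", "prompt_text": "¿Cuántos hijos tiene?", "value_kind": "free_text"},
        {"slot_name": "nombre_conyuge", "prompt_text": "¿Cómo se llama su esposo o esposa?", "value_kind": "free_text"},
        {"slot_name": "nombre_madre", "prompt_text": "¿Cómo se llamaba su madre?", "value_kind": "free_text"},
        {"slot_name": "nombre_padre", "prompt_text": "¿Cómo se llamaba su padre?", "value_kind": "free_text"}
      ]
    },
    {
      "topic_id": "life_history_lifestyle",
      "title": "Historia de vida y estilo de vida",
      "questions": [
        {"slot_name": "habito_diario", "prompt_text": "¿Qué hábito diario solía realizar con gusto?", "value_kind": "free_text"},
        {"slot_name": "habilidad_especial", "prompt_text": "¿En qué actividad era especialmente bueno o buena (tejer, dibujar, cantar, carpintería)?", "value_kind": "free_text"},
        {"slot_name": "pasatiempo_favorito", "prompt_text": "¿Cuál es su pasatiempo favorito?", "value_kind": "free_text"},
        {"slot_name": "tarea_hogar", "prompt_text": "¿Con qué actividad del hogar disfrutaba ayudar?", "value_kind": "free_text"},
        {"slot_name": "lugar_visitado", "prompt_text": "¿Qué lugar que visitó fue importante en su vida?", "value_kind": "free_text"},
        {"slot_name": "pelicula_favorita", "prompt_text": "¿Cuál es su película favorita?", "value_kind": "free_text"},
        {"slot_name": "programa_favorito", "prompt_text": "¿Cuál es su programa de televisión favorito?", "value_kind": "free_text"},
        {"slot_name": "actor_favorito", "prompt_text": "¿Qué actor, actriz o personaje le interesa más?", "value_kind": "free_text"},
        {"slot_name": "musica_favorita", "prompt_text": "¿Qué tipo de música prefiere?", "value_kind": "free_text"},
        {"slot_name": "cantante_favorito", "prompt_text": "¿Cuál es su cantante o grupo musical preferido?", "value_kind": "free_text"},
        {"slot_name": "deporte_favorito", "prompt_text": "¿Qué deporte le gusta más?", "value_kind": "free_text"},
        {"slot_name": "equipo_favorito", "prompt_text": "¿Qué equipo o deportista es relevante para usted?", "value_kind": "free_text"},
        {"slot_name": "comida_favorita", "prompt_text": "¿Cuál es su platillo favorito?", "value_kind": "free_text"},
        {"slot_name": "bebida_favorita", "prompt_text": "¿Cuál es su bebida preferida?", "value_kind": "free_text"},
        {"slot_name": "festividad_favorita", "prompt_text": "¿Qué festividad le gusta celebrar?", "value_kind": "free_text"},
        {"slot_name": "recuerdo_infancia", "prompt_text": "¿Puede mencionar algún recuerdo agradable de su infancia?", "value_kind": "free_text"},
        {"slot_name": "rutina_diaria", "prompt_text": "Describa brevemente la rutina de un día normal.", "value_kind": "free_text"}
      ]
    }
  ]
}
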