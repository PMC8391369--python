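<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="sports" description="deportes preferidos por el paciente">
    <category role="trigger">
      <pattern>DEPORTE</pattern>
      <template><random>
        <li>¿Es cierto que tu deporte favorito es <get name="deporte_favorito"/>?</li>
        <li>¿Qué deporte disfrutas más?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ DEPORTE</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>DEPORTE _</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ DEPORTE _</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>DEPORTES</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ DEPORTES</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>DEPORTES _</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ DEPORTES _</pattern>
      <template><srai>DEPORTE</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué emocionante! ¿Practicabas <get name="deporte_favorito"/> o te gustaba verlo?</li>
        <li>¿Con quién disfrutabas <get name="deporte_favorito"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>No hay problema. ¿Qué deporte te divertía?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>El deporte une a la gente. ¿Me platicas de un partido que recuerdes?</li>
        <li>Moverse da alegría. ¿Qué deporte practicabas de joven?</li>
      </random></template>
    </category>
  </topic>
</aiml>
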