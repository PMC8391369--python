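<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="sport_teams" description="equipos y deportistas relevantes para el paciente">
    <category role="trigger">
      <pattern>EQUIPO</pattern>
      <template><random>
        <li>¿Es verdad que tu equipo favorito es <get name="equipo_favorito"/>?</li>
        <li>¿Qué equipo te hace emocionarte?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ EQUIPO</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>EQUIPO _</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ EQUIPO _</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>EQUIPOS</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ EQUIPOS</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>EQUIPOS _</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ EQUIPOS _</pattern>
      <template><srai>EQUIPO</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Buen equipo! ¿Recuerdas algún triunfo de <get name="equipo_favorito"/>?</li>
        <li>¿Desde cuándo apoyas a <get name="equipo_favorito"/>?</li>
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
      <template>Entiendo. ¿Qué deportista admiras?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Los equipos nos dan grandes alegrías. ¿Cuál sigues tú?</li>
        <li>Un buen partido se disfruta acompañado. ¿Con quién los veías?</li>
      </random></template>
    </category>
  </topic>
</aiml>
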