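<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="singers" description="cantantes o grupos preferidos">
    <category role="trigger">
      <pattern>CANTANTE</pattern>
      <template><random>
        <li>¿Es verdad que tu cantante preferido es <get name="cantante_favorito"/>?</li>
        <li>¿Qué cantante te gusta escuchar más?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ CANTANTE</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANTANTE _</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANTANTE _</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANTANTES</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANTANTES</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANTANTES _</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANTANTES _</pattern>
      <template><srai>CANTANTE</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Canta precioso! ¿Qué canción de <get name="cantante_favorito"/> te gusta más?</li>
        <li>¿Alguna vez viste a <get name="cantante_favorito"/> en persona?</li>
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
      <template>Está bien. ¿Qué voz te parece hermosa?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Los cantantes nos acompañan toda la vida. ¿Cuál te gusta?</li>
        <li>Una gran voz no se olvida. ¿De quién te acuerdas?</li>
      </random></template>
    </category>
  </topic>
</aiml>
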